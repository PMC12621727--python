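"""End-to-end design pipeline: structures -> Potts models -> sequences.

A :class:`DesignJob` names the inputs (one backbone, an explicit ensemble,
or Gaussian-noise conformers), the Potts source (network checkpoint or a
raw Potts JSON), and sampler settings; :func:`run_design` featurizes every
conformer, predicts one Potts model per conformer, averages the sitewise
and pairwise terms, samples sequences with DLMC, and writes a FASTA plus a
JSON run manifest sufficient to replay the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import network as net
from .evaluation import DesignSet, write_fasta_designs
from .potts import ContractError, PottsModel, SequenceState, energy, load_potts_json
from .samplers import LCPConfig, SamplerConfig, composite_energy, dlmc_sample, lcp_penalty
from .structure import (
    FeaturizerConfig,
    StructureEnsemble,
    ensemble_diversity,
    gaussian_ensemble,
    read_backbone_pdb,
)

logger = logging.getLogger("ensdesign")

__all__ = ["DesignJob", "PipelineError", "run_design"]

DEFAULT_N_SEQUENCES = 8  # designs per backbone
DEFAULT_GAUSSIAN_K = 16  # ensemble size; 15 extra conformers + reference


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class DesignJob:
    """One design run.  Exactly one ensemble mode applies:

    * ``ensemble_mode="single"`` — the first model of ``pdb_paths[0]``;
    * ``"explicit"`` — each path (or each MODEL of a multi-model file) is a
      conformer, the first being the reference;
    * ``"gaussian"`` — reference plus ``gaussian_k - 1`` Gaussian-noise
      conformers at ``gaussian_sigma`` angstroms.
    """

    pdb_paths: tuple[str, ...] = ()
    ensemble_mode: Literal["single", "explicit", "gaussian"] = "single"
    gaussian_sigma: float = 0.0
    gaussian_k: int = DEFAULT_GAUSSIAN_K
    checkpoint_path: str | None = None
    potts_json_path: str | None = None
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    # designs are spaced 25 sweeps apart so a sticky chain still yields
    # distinct sequences
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(thinning=25))
    lcp: LCPConfig = field(default_factory=LCPConfig)
    n_sequences: int = DEFAULT_N_SEQUENCES
    seed: int = 0
    out_fasta: str = "designs.fasta"
    out_manifest: str | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ContractError("n_sequences must be >= 1")
        if (self.checkpoint_path is None) == (self.potts_json_path is None):
            raise ContractError(
                "exactly one of checkpoint_path or potts_json_path is required"
            )
        if self.potts_json_path is None and not self.pdb_paths:
            raise ContractError("network-backed jobs need at least one PDB input")


def _load_ensemble(job: DesignJob) -> StructureEnsemble:
    structures = []
    for p in job.pdb_paths:
        structures.extend(read_backbone_pdb(p))
    if not structures:
        raise PipelineError("input", "no structures parsed from PDB inputs")
    if job.ensemble_mode == "single":
        return StructureEnsemble(structures[0])
    if job.ensemble_mode == "explicit":
        return StructureEnsemble(structures[0], tuple(structures[1:]))
    if job.ensemble_mode == "gaussian":
        return gaussian_ensemble(
            structures[0], job.gaussian_sigma, job.gaussian_k, seed=job.seed
        )
    raise PipelineError("input", f"unknown ensemble mode {job.ensemble_mode!r}")


def run_design(job: DesignJob) -> tuple[DesignSet, dict]:
    """Execute the pipeline; returns the design set and the run manifest.

    Identical job + seed reproduce identical outputs.  Partial output
    files are removed on failure; errors carry the failing stage name.
    """
    t0 = time.time()
    manifest: dict = {
        "seed": job.seed,
        "n_sequences": job.n_sequences,
        "ensemble_mode": job.ensemble_mode,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    try:
        if job.potts_json_path is not None:
            try:
                model = load_potts_json(job.potts_json_path)
            except Exception as exc:
                raise PipelineError("potts-load", str(exc)) from exc
            manifest.update(K=1, forward_pass_count=0, ensemble_diversity=None)
        else:
            try:
                ensemble = _load_ensemble(job)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("input", str(exc)) from exc
            try:
                params = net.load_checkpoint(job.checkpoint_path)
                # short chains: clamp the neighbour count to L - 1
                fcfg = job.featurizer
                if fcfg.k_neighbors >= ensemble.reference.L:
                    fcfg = FeaturizerConfig(
                        k_neighbors=ensemble.reference.L - 1,
                        rbf_count=fcfg.rbf_count,
                        rbf_min=fcfg.rbf_min,
                        rbf_max=fcfg.rbf_max,
                        include_sidechain_distances=fcfg.include_sidechain_distances,
                    )
                model, n_passes = net.design_for_ensemble(params, ensemble, fcfg)
            except Exception as exc:
                raise PipelineError("network", str(exc)) from exc
            manifest.update(
                K=ensemble.K,
                forward_pass_count=n_passes,
                ensemble_diversity=(
                    ensemble_diversity(ensemble) if ensemble.K > 1 else 0.0
                ),
            )
        try:
            samples, trace = dlmc_sample(model, job.sampler, job.lcp, job.n_sequences)
        except Exception as exc:
            raise PipelineError("sampling", str(exc)) from exc
        alpha = model.alphabet
        seqs = [SequenceState(s, alpha) for s in samples]
        records = []
        for s in seqs:
            e_potts = energy(model, s)
            e_comp = composite_energy(model, s, job.lcp)
            records.append(
                {
                    "sequence": str(s),
                    "potts_energy": e_potts,
                    "lcp_penalty": (
                        lcp_penalty(s, job.lcp) if job.lcp.enabled else 0.0
                    ),
                    "composite_energy": e_comp,
                }
            )
        # rank designs by composite energy, best (lowest) first
        order = np.argsort([r["composite_energy"] for r in records], kind="stable")
        seqs = [seqs[i] for i in order]
        records = [records[int(i)] for i in order]
        dset = DesignSet(
            tuple(seqs), {"seed": job.seed, "K": manifest["K"]}
        )
        headers = [
            f"design_{idx}|energy={r['composite_energy']:.4f}"
            f"|K={manifest['K']}|seed={job.seed}"
            for idx, r in enumerate(records)
        ]
        manifest.update(
            designs=records,
            acceptance_rate=trace.acceptance_rate,
            sampler={
                "burn_in": job.sampler.burn_in,
                "thinning": job.sampler.thinning,
                "dlmc_step_size": job.sampler.dlmc_step_size,
                "mh_correction": job.sampler.mh_correction,
            },
            lcp={"enabled": job.lcp.enabled, "weight": job.lcp.weight},
            wall_time_s=time.time() - t0,
        )
        write_fasta_designs(dset, job.out_fasta, headers=headers)
        if job.out_manifest:
            with open(job.out_manifest, "w") as fh:
                json.dump(manifest, fh, indent=1)
        logger.info(
            "design run complete: %d sequences, K=%s, %.2fs",
            job.n_sequences, manifest["K"], manifest["wall_time_s"],
        )
        return dset, manifest
    except Exception:
        for p in (job.out_fasta, job.out_manifest):
            if p and Path(p).exists():
                Path(p).unlink()
        raise
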