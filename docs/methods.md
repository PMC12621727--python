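# Methods

## The Potts sequence model

A Potts model over length-`L` sequences from an alphabet of size `A`
(default: the 20 canonical amino acids in the fixed order
`ACDEFGHIKLMNPQRSTVWY`) assigns

```
E(S) = Σ_i h[i, s_i] + Σ_{{i,j} ∈ edges} J_{ij}[s_i, s_j]
p(S) = exp(−E(S)) / Z,    Z = Σ_S exp(−E(S))
```

Energies are dimensionless (units of kT at sampling temperature 1).
Couplings are stored as one dense `A×A` block per *unordered* site pair,
axis 0 bound to the smaller site index; accessors transpose for `(j,i)`
queries. This sparse-edge storage matches models derived from k-NN
structure graphs, where the edge count grows linearly with `L` rather than
quadratically.

`enumerate_distribution` materializes the exact Boltzmann distribution in
the log domain (log-sum-exp, safe for |E| up to ~700) and refuses above a
configurable cap of 10^6 states; it is the oracle against which samplers
and identities are verified.

### Gauge fixing

`(h, J)` are not identified: per-site constant shifts and row/column
shifts between couplings and fields leave every probability unchanged.
`apply_zero_sum_gauge` maps to the canonical representative with zero
row/column means in every coupling block and zero-mean per-site fields
(the overall constant is dropped, changing `log Z` but no probability).
All parameter comparisons (e.g. coupling recovery) happen in this gauge.

### Ensemble averaging

`average_models` takes the weighted mean of fields, and of couplings over
the *union* of edge sets with absent blocks treated as zero (an
intersection would silently discard interaction information). Because `E`
is linear in the parameters, `energy(avg, S)` equals the weighted mean of
per-model energies exactly — not approximately — and therefore the
averaged model's Boltzmann distribution is the renormalized weighted
geometric mean (product of experts) of the member distributions. Uniform
weights `1/K` are the default and the condition under which the pipeline
operates; non-uniform weights are an extension hook. The same identity in
autoregressive form — softmax of averaged logits equals the normalized
geometric mean of softmaxed distributions — is implemented in
`geometric_mean_combine` and exercised by tied conditional decoding.

## Samplers

Both samplers target `p(S) ∝ exp(−(E(S) + λ·LCP(S))/T)`.

**DLMC** (`dlmc_sample`): each step proposes a substitution at every site
simultaneously; site `i` draws residue `a` with probability
`∝ exp(−Δ_i(a)/(2T) − 1[a≠s_i]/(2α))` where `Δ_i(a)` is the composite
local energy and `α` is the step size (default 1.0; the `1/(2α)` term is a
laziness penalty controlling how many sites flip per proposal). With the
Metropolis–Hastings correction (default on) the joint proposal is
accepted with the standard reverse-proposal ratio, so the chain is exact
for any step size; the correctness tests would catch any variant that is
not. Small step sizes behave like single-site Metropolis (high
acceptance); large ones move many sites per step (lower acceptance on
sharp landscapes — the acceptance rate is surfaced in the trace, never an
exception).

**Gibbs** (`gibbs_sample`): systematic scan over a seeded per-sweep site
permutation, each site resampled from its exact full conditional;
rejection-free. It serves as the independent cross-check on DLMC.

Defaults: constant temperature 1.0 (the Boltzmann model as written;
linear/geometric schedules can be passed as arrays), burn-in `10·L`
sweep-equivalents, thinning 1. The design pipeline spaces successive
designs 25 sweeps apart so that sticky chains still emit distinct
sequences. All randomness is pre-drawn from a seeded numpy Generator, so
chains are bit-reproducible across platforms and independent of whether
the numba-compiled or pure-Python kernel runs.

### Local composition perplexity (LCP)

Low-complexity sequences are penalized through window perplexity: for
every length-`w` window (default 16), the composition is smoothed with a
pseudocount (default 0.1), its natural-log entropy `H` computed, and the
window contributes `max(0, P_min − exp(H))²` with `P_min` defaulting to 8
effective residue types. The squared hinge is smooth at the floor and its
single-site deltas are cheap (only windows covering the mutated site
change). The functional form and defaults are this package's choices; the
restraint is validated behaviourally (zero on diverse windows, positive on
homopolymers, measurably suppresses homopolymer windows during sampling),
not against any external implementation.

## Structure handling and featurization

Backbones carry N/CA/C/O coordinates per residue (Å); PDB I/O goes through
biotite, with multi-model files yielding one structure per MODEL record
and a `reject` (default) or `drop` policy for residues with missing
backbone atoms. Multi-chain inputs are concatenated; inter-chain edges are
allowed and a same-chain flag marks chain breaks.

`kabsch_rmsd` implements least-squares rigid superposition via SVD with
reflections excluded. Gaussian ensembles add i.i.d. zero-mean noise
(std σ per coordinate axis) independently to every atom — the simplest
reading of coordinate noise; a per-residue rigid-body alternative would
need a different generator and is intentionally not implied. Ensemble
diversity is the mean superposed CA RMSD of conformers to the reference.

Features are all rigid-motion invariant:

* node: sin/cos of φ/ψ/ω (zeros at termini and chain breaks);
* edge (per k-NN neighbour, k default 30 on CA–CA distances): Gaussian
  RBF encodings (16 centers evenly spaced on [2, 22] Å, width = spacing)
  of the 16 backbone atom-pair distances, the signed sequence separation
  clipped to ±32 and scaled, and the same-chain flag. An optional RBF
  channel of sidechain reference-point distances is appended when enabled
  and coordinates are supplied.

Neighbour ordering sorts quantized squared distances (1e-6 Å²) with index
tie-breaks, so the k-NN table is stable under rigid motions despite
floating-point jitter and the exact ties of ideal geometries. k and the
RBF grid are conventional values for message-passing inverse-folding
models, exposed in `FeaturizerConfig`; no test depends on the specific
constants.

## The toy network

`potts_net` maps a feature graph to a Potts model: 3 encoder + 3 decoder
message-passing layers at hidden width 128 by default (a `large` preset
uses 5 + 5 at width 256); decoder layers also update edge states and apply
*no* causal mask, so one forward pass yields every field and coupling.
Fields are a linear projection of final node embeddings; each undirected
coupling block is the transpose-symmetrized average of the two directed
edge-embedding projections, which makes the stored blocks well-defined
regardless of direction.

Training minimizes the mean sequence pseudolikelihood
`−(1/L) Σ_i log p(s_i | s_−i)` of predicted models against paired
sequences. Exact likelihood is intractable for Potts models;
pseudolikelihood is the standard consistent surrogate and is exactly what
a non-causal decoder supports. The message-passing trunk is a
deterministic random featurizer fixed by the init seed; only the
field/coupling projection heads are trained. This makes the objective
convex in the trainable parameters, the analytic gradient a two-line
`indicator − conditional` residual chained through linear heads, and
desk-scale training reliable within CPU seconds — at the cost that the
trunk itself never adapts, which is an accepted limitation of the toy
(shared-graph items are batched, so an epoch is a handful of vectorized
array operations). Adam with learning rate 0.05 and weight decay 1e-4 on
the head weights are the defaults.

`design_for_ensemble` featurizes and evaluates the network once per
conformer — exactly K forward passes, verified by an instrumented counter
— then averages parameters uniformly. Sampling any number of sequences
afterwards costs no further network evaluations.

## Synthetic data

The fixtures module builds everything tests need:

* **Toy backbones** from ideal internal coordinates (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å, standard angles) by sequential NeRF
  placement; helix φ/ψ = (−60°, −45°), extended (−135°, 135°), plus a
  Gaussian-perturbed variant. Consecutive CA–CA distances come out at the
  canonical 3.80 Å.
* **Random Potts models** with centered Gaussian fields/couplings on a
  seeded random edge subset of `round(density · L(L−1)/2)` pairs.
* **Rule-based structure→sequence datasets**: varied backbones from a
  seeded two-state (helix/extended) φ/ψ chain; sequences assigned by a
  documented geometric rule — CA-neighbour count within 10 Å defines
  burial, buried sites (≥7 neighbours) cycle through hydrophobic residues
  `LVIFAM` by burial depth, exposed sites take K/E with charge
  complementarity at the nearest earlier spatial contact (<9 Å, |i−j|>3) —
  plus 5% uniform label noise. The stored backbone is then perturbed at
  `noise_sigma` (default 0.1 Å) so observed geometry is an imperfect
  witness of the rule's input. The rule is chosen to be learnable by the
  toy network within CPU minutes and makes no biological claim: passing
  tests show the machinery recovers a geometry-determined sequence signal,
  not that it reproduces real protein sequence statistics.

All generators are pure functions of their spec, seed included.

## Canonical experiment conditions (`ensdesign.experiments`)

* **PoE identity**: 20 random instances, K ∈ [2,4], L ∈ [2,5], A ∈ [2,4];
  total variation between the averaged model's enumerated distribution and
  the renormalized geometric mean is at machine precision (checked < 1e−10).
* **Sampler exactness**: fully connected L=4, A=4 model with unit-scale
  parameters; 5 chains of 1e5 thinned samples (DLMC thinning 4, Gibbs 1,
  burn-in 1000); worst-seed TV against enumeration < 0.02. The model
  fixture seed (1) is fixed by a sampler-independent rule: the smallest
  seed whose exact distribution has an i.i.d. multinomial TV floor ≤ 0.011
  at 1e5 draws, so the check measures sampler error, not the flatness of a
  particular random realization.
* **Coupling recovery**: 200 sequences drawn exactly (by enumeration) from
  a random L=8, A=4 model (edge density 0.3, field scale 0.5, coupling
  scale 1.0); the network sees one Gaussian-perturbed backbone (σ=1 Å)
  whose k=7 graph covers all pairs; 800 training epochs; Pearson r between
  true and predicted couplings in the zero-sum gauge > 0.5. The irregular
  backbone matters: on an ideal helix, symmetry-equivalent edges have
  identical features and the network cannot assign them distinct
  couplings.
* **Ensemble robustness**: 5 seeds; per seed a fresh 80-structure,
  length-28 rule dataset (20% held out), hidden width 48, 120 epochs.
  For each held-out backbone, conformers are drawn at σ=0.8 Å and
  conditional-argmax recovery of the single-conformer model is compared
  with the 8-conformer averaged model sharing the same first conformer
  (paired). Ensemble averaging recovers more of the native sequence on
  every seed tested; the assertion is on the 5-seed means.
* **LCP effect**: L=24 field-only model biased −6 toward leucine; window 8,
  floor 4, weight 20; homopolymer-window counts with the restraint are
  compared against the unrestrained chain over 5 seeds.

Problem sizes throughout are deliberate desk-scale choices so the full
suite runs in a few CPU minutes; they are the package's canonical study
conditions, not tuned quantities.

## Known limitations

* The trained component is a toy: fixed random trunk, synthetic rule data,
  lengths ≤ ~60. Nothing here reproduces a production inverse-folding
  model's sequence recovery, and no folding-based designability evaluation
  (self-consistency RMSD, pLDDT) is included — those require external
  structure predictors and are out of scope by design.
* Ensembles come from user files or Gaussian noise; generative-model
  conformer sampling (diffusion partial noising, backrub) is external.
* PSSMs are consumed, never built: MSA search, weighting, and gap handling
  are out of scope.
* Best-of-N design selection ranks by composite Potts energy only;
  external designability filtering is downstream.
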