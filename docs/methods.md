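# Methods

This note records the model behind `dfmalign`, the meaning and defaults of
every tunable parameter, the numerical choices that matter for
reproducibility, and the known limitations.

## 1. Dynamic fingerprint matrices

Given a conformational ensemble of a protein — `F` frames of `N` Cα
coordinates, in Å — the *dynamic fingerprint matrix* (DFM) is

```
DFM[i, j] = std over frames of  |r_i(t) − r_j(t)|
```

the standard deviation of the inter-residue distance time series. The
population estimator (`ddof = 0`) is the default; `compute_dfm(...,
ddof=1)` selects the sample estimator. The matrix is symmetric,
non-negative, and exactly zero on the diagonal.

Because it is built from internal distances only, the DFM needs no
structural superposition and is invariant under any per-frame rigid motion
(verified to 1e-8 Å in the tests). Rigidly coupled residue pairs give
near-zero entries regardless of how mobile each residue is in the lab
frame; entries grow only with *relative* motion.

Derived per-residue summaries:

- **dynamic profile** — row `k` of the DFM: how residue `k`'s distances to
  all others fluctuate;
- **average fluctuation profile** — the row means (including the zero
  diagonal by default), a superposition-free mobility index;
- **RMSF** — the classical superposition-based root-mean-square
  fluctuation, provided for comparison. `fit=True` (default) performs an
  iterated Kabsch superposition to the mean structure until convergence.

Memory: distances are accumulated in frame blocks (~20 M floats per block)
into one `(F, N, N)` array, and the standard deviation uses the standard
two-pass formula, so accuracy does not depend on the chunking.

## 2. Pairwise match scoring

An alignment of proteins A (`N_A` residues) and B (`N_B` residues) is a
list of matched columns `(α_k, β_k)` with both index sequences strictly
increasing (monotone, gaps allowed, no crossings).

For each unordered pair of columns `k < l`, the two fingerprints give one
entry each: `a = DFM_A[α_k, α_l]` and `b = DFM_B[β_k, β_l]`. Their
dissimilarity is the mean-normalised relative difference

```
d = |a − b| / ((a + b) / 2),      d ∈ [0, 2],   0/0 → 0.
```

(`rel_diff_norm="max"` selects `|a − b| / max(a, b)` instead.) The
*pairwise match score* maps `d` to a bounded reward/penalty through a
descending logistic:

```
s(d) = s₋ + (s₊ − s₋) / (1 + exp(λ (d − x₀)))
```

with `x₀ = t − ln(s₊ / (−s₋)) / λ` chosen so that `s(t) = 0` exactly: `d`
below the tolerance `t` scores positive, above it negative. Defaults:

| parameter | default | meaning |
|---|---|---|
| `s_plus`  | `1.0`  | ceiling for a perfect match (`d = 0` gives ≈ `s₊`) |
| `s_minus` | `−1.0` | floor for a gross mismatch |
| `t`       | `0.25` | relative difference at which a pair scores 0 |
| `lam`     | `40.0` | logistic steepness (larger ⇒ closer to a step at `t`) |

The **alignment score** is the sum of `s(d)` over all unordered column
pairs. The **single match score** of column `k`,
`SMS[k] = Σ_{l≠k} s(d_{kl})`, is exactly the score drop from deleting the
column, and `S = ½ Σ_k SMS[k]`. Alignments with fewer than two columns
score 0.

A self-alignment at the defaults scores `C(N, 2) · s(0) ≈ C(N, 2)`, which
is the attainable maximum for equal-size inputs.

## 3. Optimisation by simulated annealing

The score landscape over monotone alignments is searched by multi-restart
simulated annealing (Metropolis rule `min(1, exp(ΔS / T))` for
maximisation):

- **moves** — insert one feasible column (uniformly over all feasible
  `(i, j)` slots) or remove one existing column, 50/50;
- **initial temperature** — Johnson's rule: an all-accepting pilot walk
  records the mean magnitude Δ̄ of score-decreasing moves, and
  `T₀ = Δ̄ / ln(1 / χ₀)` targets an initial acceptance ratio `χ₀`;
- **schedule** — geometric cooling `T ← c·T` after each plateau; a plateau
  ends after `plateau_min_accepts` accepted moves or when the proposal cap
  (`plateau_min_accepts / stop_acceptance`) is hit;
- **termination** — when the acceptance ratio within a plateau falls below
  `stop_acceptance` (or `max_plateaus` is reached);
- **restarts** — independent chains from random monotone alignments; the
  best-ever configuration across all restarts is returned.

| parameter | default | rationale |
|---|---|---|
| `chi0` | `0.8` | standard "mostly melted" start |
| `cooling_factor` | `0.95` | slow geometric schedule |
| `plateau_min_accepts` | `50 · min(N_A, N_B)` | scales equilibration with problem size |
| `stop_acceptance` | `0.02` | frozen-chain criterion |
| `n_restarts` | `5` | empirically ≥ 95 % optimal on enumerable instances |

The inner chain is JIT-compiled (numba) and uses O(k) incremental score
updates per move; every restart's final incremental score is re-verified
against a full rescore and a disagreement above 1e-6 is a hard error.
After annealing, columns with negative SMS are pruned iteratively (most
negative first), which can only raise the score.

For small instances `exhaustive_optimum` enumerates all
`C(N_A + N_B, N_A)` monotone alignments (guarded at 1e6) and is used as
the test oracle.

## 4. Statistical significance

Optimal alignment scores of *unrelated* fingerprints are modelled as
Gumbel (type I extreme value) with size-dependent location and scale:

```
P(S > s) = 1 − exp(−exp(−(s − μ(L)) / σ(L))),    L = N_A · N_B,
```

computed as `−expm1(−exp(−z))` for numerical accuracy in both tails.

Calibration (`calibrate`): random contiguous principal submatrices of the
requested sizes are cut from every unordered pair of reference
fingerprints and aligned; scores are binned by `L`; each bin (minimum 10
scores) gets a maximum-likelihood Gumbel fit (SciPy, moment-initialised);
`μ` and `σ` are then regressed linearly on `L` (or on `log L` with
`size_transform="log"`). `pvalue` warns when extrapolating outside the
calibrated `L` range and refuses (ModelRangeError) if the fitted `σ(L)`
is non-positive there. `is_significant` uses a strict `p < 0.05` by
default. Models serialise to JSON losslessly (bitwise-identical p-values
after a round-trip).

Synthetic reference fingerprints (`synthetic_reference_dfms`) substitute
for a curated set of unrelated proteins: random-walk backbones with
smooth, randomly-placed mobility bumps, sized 60–110 residues.

## 5. Synthetic ensemble generator

The generator produces Gaussian ensembles with a controllable mobility
pattern, in the spirit of an elastic network model:

1. a reference backbone (`helix` default: 2.3 Å radius, 1.5 Å rise,
   100°/residue; also `extended` at 3.8 Å spacing and `random_walk`);
2. a precision matrix `P = I + coupling · Laplacian(contact graph)` using
   a distance cutoff (default 8 Å) on the reference backbone;
3. the displacement covariance `K ∝ P⁻¹` rescaled so `3 K_ii =
   mobility_i²`, i.e. `mobility` is each residue's 3-D RMSF in Å;
4. per-frame displacements drawn per-axis via the Cholesky factor;
   optional AR(1) memory between frames (`frame_memory`) preserving the
   stationary marginals.

Because the model is Gaussian, the implied DFM has a closed form through
the moments of a non-central χ distribution with 3 degrees of freedom
(`implied_dfm`), which the empirical DFM matches within ~1 % at large
frame counts — used as an independent oracle in the tests.

`generate_homolog_pair` plants a shared core: protein B keeps a
`core_fraction` of A's residues (the non-core positions are A's most
mobile), perturbs the core mobilities multiplicatively by `N(1,
perturbation²)`, and splices in loop-like insertions (higher mobility) at
the indel positions, returning the planted alignment as ground truth.

## 6. Reproducibility

Every stochastic component takes an explicit seed (`SynthSpec.seed`,
`SAConfig.seed`, the `rng` argument of `calibrate`). Streams are derived
with `numpy.random.SeedSequence` and module-specific keys, so the same
seed gives bitwise-identical ensembles, alignments and calibrated models
across runs. The batch runner derives one seed per pair from the master
seed and the pair names, so all-vs-all results do not depend on input
order.

## 7. Limitations

- **Monotone alignments only.** Circular permutations and topology swaps
  cannot be represented; such pairs will score as partially similar at
  best.
- **Dynamics, not structure.** Proteins with similar fluctuation patterns
  but different folds can score as similar; the method is a complement
  to, not a replacement for, structural alignment.
- **Ensemble quality.** The DFM inherits the sampling error of the input
  ensemble; short trajectories give noisy fingerprints and weaker
  alignments (the planted-recovery tests use ≥ 4000 frames).
- **Null model scope.** The Gumbel calibration is only as representative
  as the reference set; p-values outside the calibrated size range are
  extrapolations and flagged as such.
- **Synthetic realism.** The generator is a harmonic, sequence-free
  surrogate. It is designed for controlled experiments and verification,
  not for mimicking real force-field dynamics.
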