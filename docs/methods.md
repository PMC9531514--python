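# Methods

This note records the model, its parameters, the numerical choices, and
the limits of what the synthetic experiments demonstrate.

## Model and assumptions

The method is chemocentric: a target is represented only by the chemical
structures of its known ligands, never by protein sequence or structure.
Its central assumption is that the **distribution** of pairwise chemical
similarities within a target's ligand set is a stable, discriminative
signature of the target, and that a query ligand's relationship to a
target is captured by the distribution of its similarities against that
ligand set — not by any single best score.  Divergence between the two
distributions (query-vs-class against class-vs-class) then measures
membership without a similarity cutoff.

Three further assumptions are load-bearing:

- Similarity is Jaccard–Tanimoto on fingerprint bit supports, so all
  scores live on [0, 1] and one fixed density grid serves every class.
- Distribution shapes are heterogeneous and non-Gaussian, which is why the
  densities are estimated nonparametrically (KDE) rather than by fitting a
  parametric family.
- Class membership is taken as given by the input table; no activity
  cutoff is applied (activity values are carried as metadata only).

## Pipeline parameters

| parameter | default | units | why |
|---|---|---|---|
| fingerprint length | 1024 | bits | standard folded length; shared by 3D and 2D modes so the pipeline is mode-agnostic |
| conformers per ligand | 16 | count | desk-scale default for the embedding front end; the cap stage makes downstream distributions insensitive to it |
| Q–Q conformer cap | 15,000 | conformers | bounds the pooled pair count at ~1.1e8 and evens out class imbalance; resampling is uniform without replacement, seeded |
| KDE grid | 100 bin midpoints, Δx = 0.01 | — | midpoints x_k = (k−0.5)/100 avoid evaluating at the closed endpoints where similarity scores pile up |
| bandwidth rule | Scott | — | Scott's and Silverman's rules give near-identical profiles on similarity data (L1 distance < 0.01 on 10k-sample fixtures); a fixed bandwidth is available |
| renormalize | on | — | rescales Σ p̂ Δx to 1 so profiles are comparable across sample sizes; off preserves the raw estimator |
| divergence ε | 1e−10 | density units | keeps ln finite where q(x) = 0; ~9 orders below a renormalized uniform density (1.0), so it never influences reported values at working precision |
| test fraction | 0.25 | — | 75/25 stratified split |
| forest | 500 trees, impurity splits, OOB on | — | defaults of a well-tested implementation; an optional small grid search (`tune=True`) adjusts depth and feature sub-sampling |

## The generalized divergence

KL(p|q) = Σ p ln(p/q) Δx + Σ (q−p) Δx is a Bregman divergence valid for
unnormalized nonnegative densities: pointwise p ln(p/q) + q − p ≥ 0, so
the value is nonnegative, zero exactly when p ≡ q on the grid, and it
reduces to standard discrete KL when both profiles integrate to 1 (the
correction term is then ~1e−16).  The correction term is always included:
it costs nothing when profiles are renormalized and guards the
nonnegativity invariant when renormalization is disabled.  Values are in
nats.  The target–target matrix stores KL(row | column); the transpose
holds the reverse divergences, and the matrix is generally asymmetric.

Discretization: on analytic Beta density pairs the 100-bin midpoint sum
differs from a 100,000-bin quadrature by ≤ 2.3e−3 (at divergence values of
order 1–3); the tests assert agreement within 5e−3 absolute.

## Numerical choices and degenerate inputs

- **Self-pairs** are excluded from Q–Q pooling: a conformer's unit
  self-similarity carries no inter-ligand information and biases the
  density's right tail.
- **exclude_self** (on by default during feature construction) removes a
  training ligand's own conformers from the class side of its own-class
  Q–L vector; leaving them in plants unit similarities that leak the
  label.
- **Zero-variance score sets** (e.g. a class whose pooled scores are all
  1.0) defeat automatic bandwidth rules; the estimator falls back to a
  fixed bandwidth of 0.5·Δx = 0.005 instead of failing.
- **Boundary handling** is plain renormalization, no reflection.  The
  consequence, measured on uniform(0,1) samples at n = 10,000: the flat
  density is inflated by ~4% and points within ~3 bandwidths of the
  edges are biased; tests therefore check flatness on (0.2, 0.8) with
  tolerances 0.15 (max) / 0.06 (mean), calibrated over 31 seeds.
- **Importance ties** in the pruning curve are broken by column order, so
  pruning curves are deterministic.
- **Seeding**: one master seed fans out to per-stage and per-class child
  seeds via `SeedSequence([seed, crc32(name)])`; editing one synthetic
  class never perturbs another's draws, and every artifact records the
  seed and a config hash.  Stage caching reuses the feature table only
  when the config hash matches.

## 3D fingerprints

The 3D backend is an extended three-dimensional fingerprint implemented
in-package: per-atom graph invariants seed 64-bit identifiers which are
iteratively re-hashed (5 iterations) with the identifiers and quantized
distances (0.4 Å resolution) of all atoms inside a radial shell growing
by 1.718 Å per iteration; every identifier at every level folds into the
1024-bit vector.  It is a pure function of coordinates and invariants,
deterministic, and torsion-sensitive (different conformers of one ligand
set different bits).  The backend is pluggable — any callable
(mol, conf_id, n_bits) → bits can replace it — because the method's
contribution is distribution modeling and divergence features, not any
particular fingerprint.  Conformers come from ETKDG distance-geometry
embedding with an MMFF94 minimization pass, seeded.  2D mode uses Morgan
radius-2 fingerprints, one per ligand.

## What the synthetic generator does and does not emulate

Each synthetic class owns a set of core bits; ligand prototypes set core
bits with probability p_core and background bits with p_noise, and each
conformer flips prototype bits with a small jitter probability.  This
reproduces the features the pipeline actually consumes: bounded, skewed,
class-specific intra-class similarity distributions; conformational
spread; controllable class overlap (shared core bits).  Study conditions
used throughout the tests and the acceptance script: K = 5 classes, 200
ligands × 4 conformers, 1024 bits, disjoint 48-bit cores, p_core = 0.9,
p_noise = 0.02, jitter = 0.02, cap 15,000.

It does **not** emulate: real scaffold multimodality within a class
(similarity densities here are unimodal), correlated bit co-occurrence
from shared substructures, class-size imbalance of real target panels, or
any 3D geometry.  Consequently the perfect accuracies on the default
study conditions demonstrate that the pipeline is correct and that the
KLD feature carries the class signal — not that comparable accuracy is
expected on real target panels, where class overlap (ligands shared
between targets) is the dominant error source.  The generator exposes
`core_overlap` precisely to study that regime: increasing overlap
degrades accuracy monotonically in expectation.

A related observation: with identical generative parameters the *shapes*
of different classes' Q–Q densities are similar, so the target–target KLD
matrix has small off-diagonal entries even though the classes occupy
disjoint bit subspaces.  Discrimination comes from the Q–L densities —
a query against a foreign class produces a sharply different (low-mass)
similarity distribution — which is why the feature table separates
perfectly while the Q–Q matrix alone would not.

## Design choices where the design was open

- Multi-class single-label formulation with one confusion matrix over K
  targets (rather than K one-vs-rest binary models): matches labeling
  queries with a target index 1…K.
- Q–L vectors pool all conformer × conformer scores rather than a
  per-conformer max: the vector is treated as a raw column of the
  pairwise similarity matrix, and pooling preserves the distributional
  signal that the max discards.
- Pooled score multisets are stored flat, never as square matrices: only
  the distribution is consumed downstream.
- ROC is one-vs-rest per class from predicted class probabilities.
- Out-of-set support in both directions: a query label without a density
  contributes rows but no feature column; evaluation counts registered
  out-of-set rows against overall accuracy while excluding them from
  per-class metrics.
- The percentile-rank box plot is provided as an experimental diagnostic
  (`plots.percentile_rank_boxplot`); its exact published construction is
  ambiguous, so it should be read qualitatively.

## Problem sizes and runtimes

The test suite runs the study conditions once (~35 s on one CPU:
1,000 queries × 5 classes, 4,000 conformers, 500-tree forest) plus
desk-scale unit fixtures; the seed-stability check uses a 5,000-conformer
class capped at 2,000 (the cap must be below the class size for
resampling seeds to matter at all).  The acceptance script repeats the
study end to end in ~35 s.  Scaling to panel sizes of ~15,000 conformers
per class raises the Q–Q stage to ~1.1e8 packed-popcount pairs per class,
which the blocked bit-kernel streams without materializing a dense
matrix.

## Known limitations

- KDE boundary bias near 0 and 1 (no reflection), as quantified above.
- The built-in 3D fingerprint is not bit-compatible with any external
  implementation; cross-study fingerprint files should be regenerated
  with one backend.
- Q–Q densities are built once on the full (capped) class, including
  ligands later assigned to the test split; only the query's own
  conformers are excluded from its features.  Label leakage through
  shared density estimation is second-order (any single ligand
  contributes O(1/n) of a class's pooled scores) but not zero.
- Alternative similarity metrics (cosine, Soergel) and learners are
  deliberately out of scope for this version.
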