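# Methods

## Self-organizing map

The SOM is a rectangular, planar (non-toroidal) grid of `nx × ny`
neurons, each holding a weight vector in the normalized descriptor
space. Training is classic on-line competitive learning:

* **Winner**: the neuron minimizing the Euclidean distance ‖x − w‖ to
  the presented object; ties go to the smallest row-major index
  `i·ny + j`, which makes results independent of floating-point
  vagaries and object order.
* **Update**: every neuron moves toward the object,
  `w ← w + η(t) · a(d, r(t)) · (x − w)`, where `d` is the Chebyshev
  grid distance to the winner and `a(d, r) = max(0, 1 − d/(r + 1))` is a
  triangular (linearly decaying) neighborhood — square rings shrink to
  winner-only updates as the radius reaches 0.
* **Schedules**: learning rate η and radius interpolate linearly across
  epochs, by default η 0.5 → 0.01 and radius `max(nx, ny) − 1` → 0 over
  100 epochs. Each object is presented once per epoch in an order
  reshuffled from the run seed.
* **Initialization**: weights uniform in [0, 1] from the run seed —
  natural because inputs are min-max normalized. Identical seed and
  inputs give bit-identical weights.

These specific choices (triangular neighborhood, Chebyshev metric,
planar boundary, linear schedules) follow the classic
counter-propagation literature; published map layouts depend on an
implementation whose schedules are not public, so neuron-for-neuron
layout reproduction is out of scope — cluster structure and fit
statistics are the reproducible quantities.

Normalization maps each column to [0, 1] by min-max scaling and records
the per-column scale for exact inversion; constant columns (degenerate
descriptors) map to 0.5 and are flagged rather than rejected, so a
single flat descriptor cannot abort a pipeline while remaining
auditable.

## Counter-propagation ANN

The CPANN adds an output layer in one-to-one correspondence with the
Kohonen layer. The winner is chosen from the **input** layer only; the
output weights receive the same `η · a` correction toward the target.
After training the network is a lookup table: a query returns the output
weights of its winning neuron, so predictions take at most `nx · ny`
distinct values. With ≥ as many neurons as well-separated objects and a
radius annealed to 0, the network approaches exact recall; with one
neuron it converges to the target mean.

Fit statistics follow QSAR convention: R² is the squared Pearson
correlation between observed and predicted values and RMSE is computed
on the normalized targets (both descriptors and targets are min-max
normalized before training). The residual form `1 − SS_res/SS_tot` is
reported alongside as `r2_resid`. Leave-one-out cross-validation
retrains from scratch for every fold with a per-fold seed derived as
`SeedSequence([master_seed, fold]) mod 2³¹` (exposed as `fold_seed`),
and Q²_cv / RMSE_cv are computed exclusively from held-out predictions.

## Analysis procedures

* **Average sum** — per-compound arithmetic mean over all protein
  columns; the modeling target.
* **Top-k average** — proteins ranked by their mean Bscore across all
  compounds (the only compound-independent reading of "highest binding
  activity"), descending, ties broken lexicographically by protein ID;
  per-compound mean over the top k (k = 110 by default).
* **SOM reduction** — protein profiles (or transposed descriptor
  profiles) are normalized per column, mapped, and each occupied neuron
  contributes its closest and farthest member; the deduplicated union is
  bounded by 2 × occupied neurons. A 2×2 map over descriptors therefore
  yields at most 8 names; appending the two size descriptors (QPpolrz,
  TD) gives the 10-descriptor consensus set.
* **ΔBscore** — difference of per-compound average Bscores from a
  reference compound (pristine C60, the least-active entry; the
  workflow defaults to the compound with the lowest average). Deltas are
  reported unrounded.
* **Activity sectors** — active > 5 500, moderate > 5 000, low
  otherwise, in Bscore units; boundaries belong to the lower sector and
  the low class is unbounded below (the reference C60 itself scores
  below the nominal 4 000 axis floor).
* **Saturation** — sp3-atoms = 0 → unsaturated; sp3-atoms > 60 →
  saturated; in between → ambiguous, because the two populations
  genuinely overlap there. Stereo centers travel with the report but do
  not alter the label: they track sp3 counts almost one-for-one and add
  no decision boundary.
* **Correlations / PCA** — Pearson correlation matrices with a
  |CC| ≥ 0.6 pair listing; PCA on the correlation (z-scored) matrix
  because descriptor units are incommensurable. Eigenvector signs are
  fixed (largest-magnitude loading positive) for reproducibility.
  Constant columns are dropped with a warning.

## Synthetic benchmark

The generator emulates the *structure* of an FD descriptor/Bscore study,
not its chemistry. Three independent Uniform(0, 1) latents per compound
drive the 27 named descriptor columns:

* **size** → QPpolrz, TD, total surface area, molecular weight, non-H
  atoms, rotatable bonds (positive loadings; scales/offsets chosen to
  land in plausible unit ranges, e.g. molecular weight 720–1 620);
* **aromaticity** → aromatic atoms/rings/nitrogen positively, sp3-atoms
  and stereo centers negatively. The per-column noise for these two
  blocks is derived in closed form from the configured cross-correlation
  target (default −0.85): two columns sharing a latent of variance
  v = 1/12 with independent noise of sd n correlate at `v/(v + n²)`, so
  `n = √(v(1/|cc| − 1))`;
* **polarity** → H-bonding/PSA block positively, cLogP (and cLogS
  mirrored) negatively;
* remaining columns (drug-likeness, symmetric atoms) are independent
  filler.

All other columns carry Gaussian noise of sd `noise_sd` (default 0.05)
in latent units; count-like columns are rounded to non-negative integers
afterwards (their scales are large enough that rounding barely perturbs
correlations).

Bscores for protein p in cluster c (5 clusters by default) are
`offset_c + gain_c · size + N(0, noise_sd · gain)` with cluster offsets
`3 900 + 200·c/(k−1)` and gains `gain · (0.50 + 0.40·c/(k−1))`
(gain = 4 000), plus small per-protein jitter (sd 25 on offset, 1 % of
gain on gain) so protein profiles form separable clusters spanning
roughly 3 900–8 000 — the published score range — with all three
activity sectors populated. Out-of-range draws are counted and reported,
never clipped.

What passing tests on this benchmark do **not** show: real descriptor
distributions are neither uniform-latent nor linear-Gaussian, real
protein panels are not five affine clusters, and the real
activity–descriptor relationship is not a single monotone latent. The
benchmark demonstrates that the algorithms recover known structure at
study-realistic sizes and noise, not that they would achieve the same
statistics on laboratory data.

## Problem sizes and numerical choices

Default shapes follow the study setup (169 compounds, 27 descriptors,
5×5 protein map, 20×20 model map, 2×2 descriptor map, 100 epochs,
top-110 proteins); the protein panel defaults to 200 columns with a
1 117-column full-scale option used where the panel size itself matters.
Leave-one-out at the default size retrains 169 networks (~2 minutes on
one CPU); unit tests use smaller grids and epoch counts since the
contracts they check are size-independent.

Degenerate inputs: constant columns are flagged (normalization) or
dropped with warnings (correlation/PCA); correlation of a constant
vector is an error; training data outside [−0.001, 1.001] is rejected
with a pointer to `normalize_columns`. All tie-breaks (winner neurons,
distance extremes, protein ranking) are deterministic and documented.
Per-stage seeds in the workflow are derived from the master seed and the
stage name (CRC32 into a `SeedSequence`), so adding or reordering stages
never silently changes another stage's stream.

## Known limitations

* Published map layouts cannot be reproduced neuron-for-neuron (unknown
  schedules/initialization of the original implementation); statistical
  regime reproduction is the goal.
* The min/max-per-neuron rule bounds a 5×5 selection at 50 objects; a
  published selection of 57 from the same rule is not representable and
  is not imitated.
* Multi-target CPANN output layers are supported by the data model but
  validation metrics are single-target.
* The "consensus" model is a single CPANN on the merged 10-descriptor
  set; no ensembling is implied.
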