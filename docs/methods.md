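# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## The noise statistic

Heterogeneity of a reporter within one sample is quantified as

    noise = sd(y) / mean(y),   y_i = ln(x_i + 1)

where x_i are per-cell background-subtracted intensities. The log transform
is used because the plain coefficient of variation presumes approximately
normal data, while activated AR reporters are often right-skewed or bimodal,
and because it damps the inflation of CV at low mean expression. Numerical
choices: natural log (the statistic is a ratio of sd to mean of logs, so the
base cancels; the choice is cosmetic), sample (n−1) standard deviation, and
the +1 offset so that zero intensities are admissible. A sample that is all
zeros has mean(y) = 0 and the ratio is undefined; this raises rather than
returning infinity. Intensities that become negative after background or
crosstalk subtraction are clipped to 0 by default (`clip_negative`), since
ln(x+1) requires x > −1 and negatives are measurement artifacts.

## Crosstalk and brightness

Bleed-through is modeled as additive and linear: measured receiver signal =
true receiver + f × true donor. Correspondingly the correction subtracts
f × donor, and f is fitted by **zero-intercept** least squares
(f = Σxy/Σx²): a pure bleed-through model has no offset because background
has already been removed. The reference calibration for the GFP←CFP pair is
f = 0.456; it is a config value (`QuantConfig.crosstalk_factor`), never a
hard-coded constant, because the fitted value depends on filter sets.

Brightness normalization puts fluorophores of different intrinsic
brightness (eGFP 33, mCerulean 16, mCherry 15) on a common scale:
nRF = RF × B_max/B_fluor, i.e. everything is expressed in "eGFP-equivalent"
units. A second, separable step (`max_scale`) rescales a population to
[0, 1] by its maximum for histogram axes; the two are kept explicit and
independent because "normalized to the highest values" is ambiguous between
them and analyses may need either.

## ON/OFF calls

No published rule exists for calling a reporter ON, so the package uses a
control-based threshold: mean + k·sd of a non-fluorescent control
population, default k = 3 (≈0.1% false ON for a Gaussian control). k is
exposed because separation between OFF and ON modes varies by reporter.
The call is monotone in k by construction.

## Histogram comparison

Two samples are compared with a chi-square test of homogeneity on shared
equal-width bins spanning the pooled range (default 20 bins). Tail bins are
merged inward until every expected count is ≥ 5 (the usual validity rule);
empty bins carry no information and are dropped. Degrees of freedom equal
(bins after pooling − 1). The type-I error of this procedure is verified by
simulation to sit near the nominal α.

## Shape measurement and gates

Cells are segmented by Otsu thresholding, hole filling, border clearing and
connected-component labeling. Descriptors are defined on the skeleton of
each mask:

- **width** = 2 × mean distance-transform value along the skeleton;
- **length** = skeleton arc length + the axial run from each skeleton end
  to the mask boundary. Skeletonization retreats its endpoints from rod
  caps by an orientation-dependent amount, so the end extension is measured
  by marching along the local axis direction until leaving the mask; this
  recovers the cap tips to within a pixel or two regardless of where
  thinning stopped. Arc length is computed on a coarsely resampled path
  (every 4 px) because raw 8-connected steps overestimate oblique paths by
  up to 8% (staircase effect). Skeleton spurs into cap/corner boundaries
  are trimmed first (path ends whose distance value falls > 0.5 px below
  the path median);
- **curvature** = 1 − chord/arc of the skeleton path (0 for straight rods,
  1 − 2/π ≈ 0.36 for a semicircular cell);
- **angularity** = mean absolute turning angle per step, /π, measured
  between points spaced ≈ len/10 px apart to escape the 45° quantization of
  pixel steps.

The segmentation tool the reference workflow used does not publish its
curvature/angularity formulas; the definitions above reproduce the
filtering intent, and every gate window is configurable (bounds may be set
infinite to disable a gate). Default gates: area ≥ 0.1 µm², length
1.2–5 µm, width 0.1–1 µm, curvature 0–0.15, angularity 0–0.25. Intensities
are mask means (not integrated sums), removing cell-size dependence.

## Homolog filtering and co-occurrence

BLAST tabular hits are kept when e-value < the per-component cutoff
(strict) and the aligned length is within ±10% of the query length
(two-sided; the tolerance direction is not standardized, so it is
configurable), then deduplicated to the lowest-e-value hit per
(component, species). The presence/absence matrix has one row per species
carrying the anchor component; co-occurrence percentages are simple flag
counts over those rows, with conditional versions (e.g. % of LysP-positive
species that are CsiR-positive). Taxonomy is read from the input table —
never fetched over the network — because lineage databases drift and
analyses must be reproducible offline.

## Distances, neighbor joining, bootstrap

Pairwise distances use the observed mismatch proportion with **pairwise
deletion** (sites gapped in either sequence are skipped), corrected with
the generalized Jukes-Cantor formula for an a-letter alphabet:
d = −((a−1)/a) ln(1 − a·p/(a−1)), with a = 20 for proteins and a = 4 for
nucleotides. The correction diverges at p = (a−1)/a; saturated pairs are
flagged and assigned a cap (default 5.0 substitutions/site) instead of
raising, so large real alignments still produce a tree.

Neighbor joining is the classical Saitou–Nei algorithm: join the pair
minimizing Q(i,j) = (n−2)d(i,j) − r_i − r_j, limb lengths
v_i = d(i,j)/2 + (r_i − r_j)/(2(n−2)), distance update
d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2. Ties are broken by the lowest
(row, column) index; negative limb lengths are clamped to 0 with the
deficit shifted to the sister limb (preserving v_i + v_j = d(i,j)). On any
additive matrix the algorithm reproduces the generating tree's path
lengths exactly, which the tests verify against an independent NJ
implementation on random additive matrices.

Bootstrap supports use Felsenstein column resampling: alignment columns are
drawn with replacement per replicate, distances and the NJ tree recomputed,
and each internal edge of the reference tree is scored by the number of
replicates containing the same bipartition (0..n_reps; 100 replicates by
default). Supports are stored as internal node labels in Newick output.

## Synthetic data generators

`simulate_population` draws, per cell: an independent ON/OFF Bernoulli per
channel (probability `on_fraction`); ON intensities from a normal
(symmetric, Gad/Adi-like) or lognormal (right-skewed, Cad-like) marginal,
coupled across channels through a **Gaussian copula** so the marginal
families are preserved while hitting a target latent correlation; OFF cells
emit `off_level` only. Measured intensity = true + Σ bleed × donor true +
per-field background (one Gaussian draw per field and channel — the
background distribution family is not documented for real pads and Gaussian
is assumed). Both true and measured values are retained so estimators can
be validated. Note that because ON/OFF switching is independent across
channels, the measured inter-channel correlation of a mixture is diluted
relative to the copula parameter; correlation-recovery checks therefore use
fully-ON populations.

`simulate_images` plants non-overlapping spherocylinders with uniform
interior intensity, Gaussian PSF blur, and optional Gaussian or Poisson
noise; ground truth records each cell's centroid, length, width and
orientation. It does not emulate vignetting, chromatic shift, cell growth
or time-lapse motion — so passing segmentation tests demonstrate
correctness of the measurement chain, not robustness to real-microscope
artifacts.

`evolve_alignment` simulates i.i.d. columns down a tree under the a-state
equal-rates model (substitution probability along a branch of length d:
((a−1)/a)(1 − exp(−a d/(a−1))), target state uniform among the other a−1),
the generating model matched to the JC correction, so corrected distances
are consistent estimates of path lengths. No rate heterogeneity, indels or
alignment error are simulated.

`simulate_presence_table` draws independent Bernoulli regulator flags given
the anchor; defaults use the reported conditional rates of the Cad system
(CadA 0.943, CadC 0.955, LysP 0.669).

## Problem sizes and defaults

Statistical checks run at n = 1000 cells per sample (matching the >1000
cells per condition the workflow targets), 20–50 seed replicates for
recovery tests, 200 replicates for type-I error, alignments of 2000–10000
columns, and 100 bootstrap replicates — sizes at which binomial/regression
sampling error is well below the tolerances being tested while the full
suite runs in seconds.

## Known limitations

- Only the single GFP←CFP crosstalk term is modeled (no general spectral
  unmixing) and no photobleaching correction is applied.
- Shape descriptors are medial-axis re-definitions, not a bit-for-bit
  reproduction of any specific segmentation tool.
- The NJ implementation is O(n³) in taxa and comfortable into the
  low thousands of sequences; it is not optimized for much larger trees.
- Presence/absence flags treat a species as a single unit (best hit per
  species); paralog structure within genomes is not represented.
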