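# Methods

## Synthetic expression data

`syndata.simulate_counts` draws UMI counts per cell and gene from a
negative binomial with mean μ and dispersion θ (variance μ + μ²/θ); a
Poisson switch (`poisson=True` or θ = ∞) gives the equidispersed limit.
The defaults emulate a two-condition (donor vs PAH) dissociated
pulmonary-artery design: 14 populations, 3 samples per condition, ~4,800
captured cells per sample, 2,000 genes at a constant baseline mean of 1.4
counts with θ = 2 — which yields per-cell complexity (≈1,300 detected
genes, ≈2,800 UMIs) in the range of droplet scRNA-Seq of vascular tissue.
A constant baseline (rather than a per-gene mean distribution) keeps every
gene's moments analytically checkable; the cost is an unrealistically
narrow gene-mean distribution, noted under limitations.

Planted structure, all recorded in `SynthTruth`:

* **markers** — disjoint gene blocks per population, mean multiplied by
  2^`marker_log2fc` (default 2) inside the population;
* **condition response** — a gene block multiplied by
  2^`condition_log2fc` in all PAH cells;
* **mitochondrial fraction** — a 13-gene `MT-` block whose per-cell means
  are rescaled so the expected mito fraction equals a per-cell draw from
  `mito_fraction_range` (default 1–4%, i.e. below the QC cutoff, so
  default datasets lose no cells to the mito rule while the rule is still
  exercised end-to-end);
* **ligand–receptor channels** — for each (source, target, ligand,
  receptor) tuple, the ligand (receptor) gene's mean is multiplied by
  2^`lr_log2fc` (default 1.5) in the source (target) population;
* **proportions** — per-condition population proportion vectors (uniform
  unless planted).

Population labels are drawn i.i.d. per cell from the condition's
proportion vector, so realized per-sample proportions carry multinomial
noise around the planted values — exactly the sampling structure the
arcsine-t proportion test assumes.

## Synthetic vessel images

`simulate_vessel_image` renders one transverse vessel per image as
concentric rings on a (channels, rows, cols) float raster: a VWF ring at
the lumen boundary, a VCAN band from the lumen to the media's inner
radius (the neointimal/synthetic-SMC layer of a remodeled vessel), an
ACTA2 media annulus, a DCN adventitia annulus, nuclear disks, and a marker
channel lit inside a planted fraction of medial nuclei (count =
`round(fraction × n_medial_nuclei)`). The VCAN band matters structurally:
the vessel-shape segmentation combines the structural channels, so the
hole they enclose is exactly the analytic lumen disk, making the
normalized radial axis testable against the planted radii.

Nuclei are placed by rejection sampling (cap 1,000 retries, then a
placement error) with non-overlap margins; adventitial nuclei are kept
clear of the media edge so the center-in-annulus truth label agrees with
the overlap-based medial classifier. Gaussian noise of σ = amplitude /
`channel_snr` is added per pixel and the image clipped at zero;
`channel_snr = inf` gives the noise-free image used for geometric
oracles.

## QC

Three rules, each reported per cell with the triggering rule: mito
fraction > 0.05; detected genes < 200; detected genes > median +
3·MAD. The MAD is the raw median absolute deviation (no 1.4826
normal-consistency scaling) of detected-gene counts, computed per sample
when sample labels are supplied — each sample processed individually —
and the bound is strict (`>`). The mito and low-gene rules are exactly
idempotent; the MAD bound is not in general, because removing the upper
tail shifts the median/MAD slightly, so a second pass can clip a small
additional sliver (<1% of cells on default synthetic data, covered by a
test). Iterating the rule to a fixed point would restore exact
idempotence but would remove more cells than the one-shot rule as stated;
we keep the one-shot rule.

## Normalization and fold changes

`lognormalize` maps counts to `log(1 + 10⁴·count/cell_total)` (scale and
pseudocount recorded in `uns`); zero-total cells are dropped with a
warning. Fold changes are computed on the de-logged scale:
`log2((mean(expm1 x_A) + c)/(mean(expm1 x_B) + c))` with pseudocount
c = 1 — bounded for dropout-heavy genes, antisymmetric, configurable.

## Wilcoxon machinery

`rank_sum_test` uses the exact Mann–Whitney null distribution when both
groups have ≤ 25 observations and no ties, otherwise the tie-corrected
normal approximation *without* continuity correction: the correction makes
small-sample p-values conservative, and the uncorrected statistic keeps
the null rejection rate at α = 0.05 calibrated (verified on negative
binomial count data in the acceptance suite). Fully tied inputs return
p = 1. The matrix path (`find_markers`) vectorizes the same statistic over
genes and is tested for exact agreement with `scipy.stats.mannwhitneyu`.
Marker tests are Bonferroni-corrected over the genes actually tested
(after the pct/log2FC prefilter); enrichment tests use Benjamini–Hochberg
— the two corrections are deliberately not interchanged.

## Signature and cell-cycle scores

Genes are ranked by dataset-mean expression and cut into `n_bins` (24)
equal-size bins; each signature gene draws `ctrl_per_gene` (100) controls
uniformly without replacement from its bin, controls are pooled as a set,
and the score is mean(signature) − mean(controls) per cell. The draw is
seeded and mandatory. Known degeneracy: a signature whose genes occupy an
expression bin alone becomes its own control and scores ~0; bins must be
populated, which holds for realistic gene-mean spreads. Cell-cycle calls:
G1 iff both S and G2M scores ≤ 0, else the larger score's phase — cells
with near-zero scores flip between G1 and the weakly positive phase on
noise, which is inherent to the rule, not a defect.

## Proportion test

Per-sample proportions p_s are transformed asin(√p_s) (variance
stabilizing for binomial proportions; endpoints map to 0 and π/2) and the
two conditions compared by a two-tailed pooled-variance t test. Pooled
variance rather than Welch because n = 3 samples per condition makes
Welch degrees of freedom unstable; `equal_var=False` is exposed. Two
degenerate cases are defined explicitly: all transformed values identical
→ t = 0, p = 1; zero within-group variance with different means → p = 0.

## Ligand–receptor communication

Edge weight = w_ligand + w_db + w_receptor, where w_gene is the log2FC of
the gene in the population vs all other cells and w_db ∈ [0, 1] is the
database pair weight. Edges require *positive* enrichment of both partners
(log2FC ≥ 0.25, detected in ≥ 25% of cells, Bonferroni-adjusted Wilcoxon
p < 0.05): an "expression weight" for a depleted gene is not meaningful
here. Autocrine edges are included. This is the additive three-term score
itself, not a path-propagation scheme — no diffusion over a signaling
graph is attempted.

The permutation null shuffles population labels across cells **within
each sample**, preserving per-sample population sizes and sample
composition. The permuted statistic is the raw additive log2FC sum
without the enrichment gate: observed and permuted statistics are then
exchangeable under the null, which makes the add-one estimator
p = (1 + #{permuted ≥ observed})/(1 + n_perm) calibrated (uniform on its
achievable grid, KS-tested). Applying the gate inside permutations would
send almost every permuted weight to "no edge" and every observed edge to
the floor p = 1/(n_perm + 1) regardless of signal. The gate therefore
decides which edges are *reported*; the permutation decides how
*surprising* their weight is. Default n_perm = 100,000; tests and the
acceptance script use 1,000 and state so. The permutation path recomputes
only group sums via a one-hot matrix product; a naive per-population
reimplementation is kept and tested for exact agreement.

## Image quantification

* **Vessel segmentation** — structural channels combined by per-pixel
  max, Otsu-thresholded (the threshold method for this step is a package
  choice; configurable), largest connected component filled → outer mask;
  largest interior hole → lumen; lumen center of mass → probe origin.
* **Radial profiles** — 32 probes at angles 2πk/32; each probe marches
  outward in 0.25-px steps to find its lumen-boundary and outer-boundary
  crossings, then samples each channel by bilinear interpolation at 100
  positions evenly spaced between the crossings. "Rescaling to a common
  baseline" is length normalization only — intensities are never
  rescaled. Probes that leave the image before exiting the vessel are
  dropped and reported; >50% dropped is a geometry error. Probe traces
  start at the lumen *boundary*, not the center — the documented reading
  of "from lumen toward the outside".
* **Yen threshold** — 256-bin histogram over the channel's range; returns
  the bin center maximizing Yen's maximum-correlation criterion; equal to
  exhaustive search by construction and within one gray level of
  `skimage.filters.threshold_yen` on 8-bit images. Constant images are an
  error.
* **Nuclei** — Yen threshold, hole filling, watershed on the Euclidean
  distance transform with peaks ≥ `nucleus_radius` apart, minimum-area
  floor π·(r/2)².
* **Medial call** — nucleus medial iff disk-dilated ACTA2 mask (radius
  2 px default; unstated upstream, exposed in config) overlaps it and no
  VWF mask pixel lies inside it. Binary masks are speckle-filtered
  (components < 5 px removed) so shot noise neither grants nor vetoes
  medial status.
* **Marker positivity** — per-nucleus marker-mask area fraction; vessel
  summary = % of medial nuclei with fraction ≥ 0.1 (the dichotomization
  cutoff is a package choice, exposed); zero medial nuclei → summary NaN
  with a warning. Display-contrast settings (percentile clipping) apply
  only to rendered figures, never to quantification.

## Problem sizes and determinism

The default test suite and `scripts/acceptance.py` run scaled problem
sizes chosen for a laptop-class machine: 200 null datasets × 1,000 genes
for rank-sum calibration, 1,000 permutations (vs the 100,000 default) for
permutation checks, 500-cell-per-sample simulations for channel recovery
over 20 seeds, and 12–60 synthetic vessels at 256² px. Every stochastic
stage takes an explicit seed; the pipeline derives per-stage substreams
from one run seed, and reruns with the same config are byte-identical.

## What passing tests do and do not show

The generator plants exactly the structure the statistics estimate —
i.i.d. negative binomial counts, clean fold-change elevations, perfect
ring geometry. Passing recovery tests therefore demonstrates correctness
of the implementations under their own assumptions, not robustness to
what real data add: ambient RNA, doublets, batch effects, gene–gene
correlation, per-gene mean/dispersion variation, irregular vessel shapes,
uneven illumination, out-of-focus nuclei. Integration, clustering,
embedding, trajectory/velocity analysis, and database curation are out of
scope; population labels and the ligand–receptor database are inputs.
One known sensitivity: Yen thresholding adapts to whatever intensity range
a channel has, so a marker channel containing *no* true signal yields a
within-noise threshold; the speckle filter suppresses the resulting
false positivity at high SNR, but heavily noise-dominated channels remain
the method's weakest case.
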