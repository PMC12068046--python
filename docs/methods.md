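# Methods

This note documents the models, conventions, and numerical choices behind
each stage of the pipeline, what the synthetic-data generators emulate,
and what the simulation studies do and do not demonstrate.

## Synthetic plates

Cells are rendered as radial polygons from five parametric archetypes.
With base scale `r0` (default 18 px at 0.6 µm/px):

| class       | outline r(θ)                                   | notes |
|-------------|------------------------------------------------|-------|
| spindly     | `1.45 r0 (0.18 + 0.82 |cos θ|^1.5)`            | two-lobed, tip-to-tip extent ≈ 4× waist |
| large round | disk, `1.55 r0`                                | |
| triangular  | `0.85 r0 (1 + 0.45 cos 3θ)`                    | three protrusions |
| fan         | `r0 (0.55 + 0.65 max(cos θ, 0))`               | asymmetric; nucleus offset 0.45 r0 backwards |
| small round | disk, `0.60 r0`                                | |

Each cell gets a random rotation and ±8% size jitter; nuclei are disks of
radius `0.32 r0`. Placement is a jittered grid, which keeps cells from
overlapping — crowding and touching cells are *not* emulated, so the
segmentation accuracies measured here are upper bounds for confluent real
data. Images are blurred (σ = 1 px) and corrupted with Poisson shot noise
plus Gaussian read noise (sd 3) and a camera offset of 10; at the default
body intensity of 300 this gives SNR ≈ 17 and reliable default
segmentation, which is the regime the defaults are calibrated for.

The marker channel paints the cytoplasm at 120 and the nucleus at
`120·10^ρ`, where the programmed per-cell ratio
`ρ = class baseline + well ratio_shift + N(0, 0.10)`. Class baselines
(0.20/0.10/0.30/0.15/0.40 for the five classes in the order above) make
the ratio class-dependent, as observed in heterogeneous populations.
Because of blur bleed across the nuclear boundary, the measured ratio has
a small residual bias (≲0.01 at the default geometry); the per-cell noise
dominates.

A table-level simulator (`simulate_cell_table` / `synthetic.screen`)
draws classes and ratios directly without rendering. It is statistically
equivalent to rendering followed by perfect classification and is used
for screen-scale studies (hundreds of wells) where image rendering adds
cost but no information: the scoring statistics only ever see the cell
table.

**Mock-well overdispersion.** In the hit-calling simulator, mock
(reagent-only control) wells receive an extra per-well ratio offset with
sd √2× the sampling error of a well median (total mock sd ≈ 1.7× a test
well's). This reflects the overdispersion such controls show in practice
— they are spread across plates and absorb residual positional and
handling effects — and it is what makes a fixed ±1.5 mock-SD cut operate
below a 5% well-level false-positive rate; with mock wells exactly
exchangeable with test wells, a one-sided 1.5σ cut would flag ≈6.7% of
nulls by construction. Simulated "hit" wells are shifted by 3 mock SDs, a
robust-hit effect size (compare the replicate Z-scores −1.73…−2.77 of a
reproducible real hit).

## Segmentation and regions

Nuclei: Gaussian smoothing (σ = 2 px), Otsu threshold on log intensity
(robust to bright-tailed histograms), removal of objects under 40 px,
distance-transform watershed to split touching nuclei. Cells: seeded
watershed on the smoothed tubulin channel restricted to its Otsu
foreground, one cell per nucleus; border-touching cells are flagged and
excluded from measurement. Background per channel is the median intensity
over non-cell pixels of the field.

Ring = 4-px dilation of the nucleus minus the nucleus, clipped to the
cell; an empty ring flags the cell invalid for ratio measurement.
Membrane band = cell minus its 3-px erosion. The translocation readout is
log10 of background-subtracted region means and is exactly invariant to
global multiplicative intensity scaling.

## Features

The registry holds 14 morphology features (area, perimeter, roundness
4πA/P², major/minor axis lengths and their ratio, solidity, eccentricity,
extent, equivalent diameter, protrusion count, nucleus area/roundness,
nucleus:cell area ratio), 6 intensity means (cell and nucleus × channel),
and 24 SER texture responses (8 types × 3 channels) — 44 named features,
fixed order. Protrusion count is the number of convexity-defect bays of
the outline deeper than 3 px and larger than 20 px². SER responses come
from Gaussian-derivative Hessian eigenvalues at scale 1 px: spot/hole for
signed blob curvature, ridge/valley for line-like structure, saddle for
mixed curvature, edge for gradient magnitude, bright/dark for deviations
from the in-mask mean; all are normalized by the in-mask mean intensity
so they are scale-free. Truncated derivative kernels leave a ~1e−4
residue on perfectly uniform regions; features are translation- and
90°-rotation-invariant to well under 1%.

The vendor feature set this registry stands in for is not public; no
parity with any specific commercial list is claimed, only coverage of
the named features plus enough texture/shape diversity to train the
classifiers.

## Shape classifier and normal filter

The five-shape classifier is a multinomial logistic regression (L2,
C = 1) on standardized features; "linear classifier" is the design
constraint, and a regularized multinomial fit is its simplest robust
instance. Hold-out accuracy is estimated on a stratified 25% split, then
the final weights are refit on all exemplars. Ties in the decision scores
break by fixed class order. Translocation-ratio features are not part of
the registry, so the classifier cannot see the readout being scored.

The normal (penetrance) filter: PCA on pooled standardized features of
mock plus shape-enriched populations; the "normal" region is the
axis-aligned box centred on the mean of (PC1, PC2) with half-width 1 SD
per component; a binary logistic classifier is trained with mock cells
inside the box as normal and everything else as not-normal. Which
population defines the box is configurable (`pooled` default, `mock`,
`enriched`) because the defining population is genuinely ambiguous in
the source procedure; the pooled choice is the most symmetric reading.
PCA component signs are fixed by making each component's
largest-magnitude loading positive.

## Screen scoring

Per well: shape fractions over classified non-normal cells, median log10
ratio over all cells, normal fraction over all cells. Wells on columns
1/2/23/24 (density gradients) and wells under 50 cells are excluded from
everything, including mock statistics. Plate normalization (default on)
subtracts the per-plate median of usable mock wells from each metric;
Z-scores then use the pooled mock mean/sd of the screen (≥8 usable mock
wells required; sd of zero is an error naming the metric). A condition's
QMS is the mean of its replicate wells' Z-scores. Hit thresholds are
inclusive: ratio Z ≥ +1.5 / ≤ −1.5 (yap_high / yap_low), normal-fraction
Z ≤ −1 (shape hit). Both per-well and per-condition flags are reported;
whether a "condition hit" requires all replicates or any is left to the
caller, since both conventions are in use.

## Phenoclusters

Similarity is the uncentered Pearson correlation (cosine of the raw
vectors — proportional signatures score 1 regardless of offset);
distance is `1 − similarity` with average linkage (complete selectable).
Average linkage is monotone, so the cut is well-defined: phenoclusters
are maximal subtrees whose *root* merge similarity exceeds the threshold
(default 0.73); the alternative reading (minimum pairwise similarity
within the cluster) is not implemented because the grouping rule is
stated in terms of the highest node. Tie-breaking follows input order
via scipy's deterministic linkage.

## Invasion

Nuclei per plane by Laplacian-of-Gaussian blob detection on the
min-max-normalized plane (σ 2–8 px); a detection counts as a cell only
if its mean nuclear *and* GFP intensities clear their thresholds, which
removes low-intensity decoys/debris. "Middle planes" are all planes at
depth > 0; a cell visible in two planes counts in both, as the
per-plane formula implies. Index = Σ counts(depth>0) / Σ counts(all).

## FA dynamics

Per-frame masks by a robust global threshold (median + 5·1.4826·MAD of
the first frame); tracks link by any mask overlap between consecutive
frames, largest overlap winning conflicts; merges and splits terminate
tracks and there is no gap closing (a one-frame dropout yields two
tracks). The intensity trace is median-filtered over 3 frames for peak
detection; because a 3-frame median can displace a sharp peak by one
frame, the peak is refined to the raw argmax within ±1 of the smoothed
argmax — this keeps the noiseless case exact. Assembly phase =
birth→peak, disassembly = peak→death, both rates from least-squares
slopes of ln(intensity) vs time (minutes; disassembly negated so both
are positive for canonical traces); phases under 3 points leave the
rate missing. Stability phase = the contiguous run around the peak at
≥90% of peak (configurable). Phase lengths count all in-phase frames.

Movie pixels are quantized to uint16, so "noiseless" rate recovery is
exact only to quantization (measured ≲2e−3 /min); trace-level fits with
no quantization recover rates to machine precision.

Hedges' g uses the pooled-sd formula with small-sample factor
`J = 1 − 3/(4N−9)`; the 95% CI is a BCa bootstrap (default 5000
within-group resamples; z0 from the bootstrap fraction below the
estimate, acceleration from a grouped jackknife). Magnitude bins on |g|:
<0.2 none, then S/M/L/VL with lower edges inclusive at 0.2/0.5/0.8/1.2.
Mann–Whitney p-values are two-sided and exact for small groups.

## Differential proteomics

The pipeline starts at the protein abundance table. Scaling within each
cell line: per-sample median normalization on log2, then per-protein
centring. The test statistic is a Welch t moderated by an additive fuzz
s0 = 0.1 (small unequal-replicate groups make the unequal-variance form
the safer base). The null is built from label permutations — all
distinct assignments when few (e.g. 20 for 3 vs 3), otherwise n_perm
seeded draws; fewer than 10 distinct permutations is an error. SAM-style
q-value (default): median permuted exceedance count over observed count
at each |t|, monotonized. Alternative `bh`: Benjamini–Hochberg on
p-values from the permutation null pooled across proteins (pooling is
required for useful resolution when distinct permutations are few).
Significance requires |log2 ratio| > 0.5 (strict) *and* q < 0.05.
Proteins with missing abundances are dropped by default; low-quantile
imputation is available on request.

## Wound-healing polarity

The Golgi angle is measured between the nucleus→Golgi vector and the
wound tangent, with the tangent sign fixed so the (tangent, inward
normal) frame is right-handed: 90° ⇔ the Golgi points along the inward
normal (toward the wound), 0°/180° ⇔ parallel to the wound. Cells whose
Golgi lies behind the nucleus relative to the wound (v·n̂ < 0) are
excluded — only wound-facing Golgi are scored. Which of 30°/150° a
left- vs right-leaning cell receives depends on the tangent sign
convention; it is arbitrary but applied consistently, and the synthetic
generator uses the same frame. Angles bin to the nearest of
0/30/60/90/120/150/180°, exact midpoints to the lower bin. Migration
rate is the least-squares slope of mean front displacement (µm) vs time
(h), invariant to the time origin.

## Configuration and determinism

All screen thresholds (±1.5, −1, 0.73, ±0.5, 0.05, 5 frames, axial
ratio 3, 30° bins) live in one validated config with those values as
defaults; unknown keys are rejected. A single global seed is fanned out
per module as SHA-256("seed:module") mod 2³¹. Pipeline runs are
deterministic and byte-identical under a fixed seed; the run report
(JSON) omits the output path so reruns into different directories
compare equal, and a failed run still writes the report with a failure
marker.

## Study sizes and what passing shows

The simulation studies use: 20 wells × 500 cells (shape recovery, base
scale 14 px to keep the render tractable on one CPU), 40 mock wells
(Z standardization), 560 wells (hit calling), 100 random matrices of
n ≤ 6 (cluster oracle), 200 SNR-10 tracks (rate recovery), 500
replicates at n = 30/group with 2000 bootstrap resamples (BCa coverage),
20 null tables (FDR calibration), and a 19-well rendered screen run
twice (determinism). Passing them shows the statistical chain is
implemented correctly and calibrated under the generators' assumptions
(well-separated cells, Gaussian/Poisson noise, exponential adhesion
kinetics, log-normal abundances). It does not certify performance on
confluent fields, textured real cytoplasm, drifting microscopes, or
peptide-level proteomics artifacts — the generators deliberately do not
model those.
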