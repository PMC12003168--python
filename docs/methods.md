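# Methods

This note records the models, conventions and open design choices behind
`gliaquant`, in the order data flows through the package.

## Image operators (`gliaquant.imgops`)

All operators act on `ChannelImage`, a 2D grid with a physical pixel size
(µm/px); every spatial parameter is given in micrometres and converted
internally, so results are invariant to resampling up to discretization.

**Fourier size filter.** "Keep structures above X µm" is implemented as a
radially symmetric Gaussian low-pass whose kernel FWHM equals the cutoff
(σ = X/2.355). This gives a closed-form transfer function
exp(−2π²σ²/λ²): a sinusoid of period X is attenuated below 5%, of period
10X retained above 96%, and the DC component (image mean) is preserved
exactly. The complementary high-pass (`pass-small`) returns input minus
low-pass. A cutoff below one pixel is a no-op with a warning.

**Direction of the size filter per stage.** The DAPI stage low-passes at
2.6 µm (denoising that retains 5–8 µm nuclei). For the plaque channel the
same direction at 26 µm would convolve ~20 µm plaques with an 11 µm-σ
kernel: in our tests a 255 µm² deposit thresholded at 982 µm² (≈4×) and
nearby plaques merged, which defeats the strict 130 µm² object rule. The
plaque stage therefore defaults to the background-removal direction —
suppress structures broader than 26 µm, keeping deposit outlines sharp —
under which the same deposit is recovered at 255 µm². Both stages accept
either direction (`dapi_filter_mode`, `plaque_filter_mode`); the phrase
"frequency filter for structures above X µm" is genuinely ambiguous and we
do not claim to reproduce any particular macro bit-for-bit.

**Rolling ball.** Sternberg's definition: the background is the grayscale
opening of the intensity surface by a ball of the stated physical radius
(implemented as erosion/dilation with the ball's height profile as a
non-flat structuring function); the result is max(img − background, 0).
For radii much larger than a pixel the opening runs on a min-pooled,
downscaled image (kernel capped at 20 px) and the background is bilinearly
upsampled — the classical shrink strategy; on a flat-plus-narrow-peak test
the error against the exhaustive opening is < 0.03 intensity units.

**Otsu threshold.** 256 equal-width bins spanning the observed min–max;
the split maximizing between-class variance is found (first maximum =
smallest threshold) and the upper edge of the last background bin is
returned, so classifying by `value > threshold` reproduces the optimal bin
partition exactly. Returning a bin *center* (a common convention) can
misclassify the largest background value when it sits alone in the split
bin — with only ~50 cell means per image this single-value flip measurably
corrupted positivity calls, hence the edge convention. Thresholds are
shift-equivariant up to bin granularity; constant input raises.

**Component labelling.** 8-connected; objects are kept when area
(pixels × pixel_size²) exceeds the floor strictly ("above 130 µm²"), and
survivors are relabelled 1..K in raster order of their first pixel.

## Segmentation (`gliaquant.segment`)

Nuclei: size filter (2.6 µm) → Gaussian blur (σ = 0.52 µm) → Otsu → hole
filling → Euclidean distance transform (µm sampling) → seeds at distance
maxima ≥ 4 µm apart → watershed → area floor 10 µm². The watershed seed
separation and nucleus area floor are not part of the published protocol;
4 µm and 10 µm² match typical nuclear dimensions and are configurable. The
reference nuclei segmenter is classical rather than a pretrained
star-convex network: acceptance here is ground-truth recovery on synthetic
blobs, where the classical chain achieves 100% one-to-one matching; a
`segmenter` hook accepts any callable returning the same `LabelMap`
contract so a learned model can be dropped in and scored by the same suite.

Plaques: size filter (26 µm, background-removal direction) → rolling ball
(52 µm) → Otsu → 3×3 binary opening (despeckle) → objects strictly above
130 µm². The despeckle step exists because Otsu on a signal-free noise
field marks ~40% of pixels foreground, which percolates into a single
image-spanning component that would pass any area floor; a one-pixel
opening removes pixel-scale speckle while leaving ≥130 µm² (≈1400 px)
objects intact. It is configurable (`despeckle`).

## Per-cell quantification (`gliaquant.quantify`)

Marker expression is the mean intensity over each segmented nuclear region.
Positivity is Otsu per image on the cell-level means, never shared across
images; fewer than two distinct means yields an indeterminate flag.
Distance to plaque is measured from the cell centroid to the nearest plaque
pixel center (0 inside a plaque) — a band "around" the object, not distance
between centroids. The proximity selection is Iba1⁺ AND distance ≤ 30 µm.

Expression profiles: histograms over bin edges fixed across all images
(default 20 equal-width bins spanning the pooled min–max of the supplied
records — the bin count and range are not specified in the protocol we
follow; fixing edges globally keeps images comparable, and per-image edges
are available by passing explicit edges). Each image's histogram is divided
by its own sum (bin widths are constant, so integral normalization equals
count normalization); animals pool their images by element-wise median;
groups report mean ± s.e.m. across animals (n−1 in the standard deviation).

The count/coverage metrics are plain ratios: marker⁺/reference⁺ counts,
cells per stated ROI area (e.g. 2×10⁴ µm²), and marker mean gray over DAPI
mean gray within an ROI.

## Morphometry (`gliaquant.morphometry`)

Exact formula application, no rounding: d = 2√(A/π), g = d_in/d_out,
sheath = d_out − d_in; annotation rows with A_in > A_out raise. Grid
sampling interprets "axons touching the angles" as masks covering grid
intersection points, visited in row-major order with a deterministic
first-n selection (grid origin configurable; an alternative origin shifts
which axons qualify but not the statistics of the selection). The group
test is Kruskal–Wallis with tie correction; pairwise follow-ups are
two-sided Mann–Whitney U (exact when both groups have ≤ 10 untied
observations, normal approximation otherwise) with Bonferroni
multiplication capped at 1. Dunn's test was considered and not included:
the protocol names only Kruskal–Wallis and Bonferroni. The test operates
per axon with `animal_id` retained, so a per-animal aggregation can be
applied upstream when pseudo-replication is a concern.

## Phagocytosis (`gliaquant.phagocytosis`)

Grades: 0 beads → 0; 1–3 → 1; 4–6 → 2; 7–10 → 3; >10 → 4. The per-grade
percentage uses *all counted microglia* as denominator, so the grade
percentages sum to the phagocytic percentage and the index
Σ g·pct[g] ∈ [0, 400] equals 100 × mean grade — an identity the tests
assert exactly. The alternative base (percentage among phagocytic cells
only) is available via `denominator="phagocytic"`; which base the original
figure legend intended is ambiguous, and the default is chosen for its
additivity. Aggregation: field of view → animal (mean over fields) →
group (mean ± s.e.m. over animals).

## Compositional statistics (`gliaquant.compstats`)

QC removes genes first (detected in fewer than 3 cells), then cells on the
gene-reduced matrix (< 200 detected genes, < 500 or > 30 000 UMIs,
mitochondrial fraction strictly above 5%); all inequalities are strict as
phrased, the filter is idempotent, and a per-criterion report is returned.
Clusters with strictly more than 50% flagged doublets are dropped whole;
flagged cells in other clusters are kept (the rule is cluster-level).

Proportion ANOVA: per-sample proportions, per-cell-type one-way F across
genotypes, Holm step-down across the cell types tested in one call, with
Bartlett and Shapiro–Wilk reported as diagnostics that never gate the
test. Groups with no variation at all are reported as F = 0, p = 1.

kNN/KL statistic: for each cell, the label distribution over its k = 30
Euclidean nearest neighbors (self excluded) is compared to the global
label distribution by KL divergence in nats (0·ln 0 = 0). The embedding is
an input — the clustering pipeline that produced the original embedding is
out of scope. Controls permute labels uniformly on the same graph with a
caller-supplied seed; summaries are emitted per cell, per label class and
overall, since which aggregation the original analysis used is not
specified. Note on exactness: on a ring of alternating labels every
punctured ±k/2 window is balanced only when k is divisible by 4; k = 30
leaves each window at 14/16 (KL ≈ 0.0022 nats), a discrete artifact the
tests pin analytically, with the exact-zero case exercised at k = 32.

DEG filtering: significant ⇔ log2FC > 0.25 and FDR < 0.01, both strict
(values exactly at a threshold are excluded). Symbols are matched exactly
after whitespace trimming; duplicates raise; no ortholog mapping.

## Synthetic data (`gliaquant.synthdata`)

The generators emulate the statistical structure of the real inputs, not
their appearance. Seeding: generator i draws from
`default_rng([seed, STREAM_i])`, so each generator's output is
byte-identical for a given seed regardless of what else runs.

**Scenes.** 512×512 px at 0.3 µm/px (153.6 µm field), 50 nuclei of radius
2.5–4 µm, 3 plaques of lobe radius 7–12 µm — the field density of a
cortical ROI near plaques. Channel intensities are declared conventions
(no instrument model): DAPI mean 120, Iba1⁺ 150 vs Iba1⁻ 20 (≥ 5× the
noise sd apart), Clec7a on Iba1⁺ cells = 200 − 1.5·distance-to-plaque
(Iba1⁻ cells sit at 15), plaques 180, additive Gaussian noise sd 5 plus a
smooth cosine background of amplitude 10 (Poisson noise behind a flag).
Nuclei render as Gaussian-profile disks (σ = r/2, truncated at the disk
edge) normalized on the pixel grid so the mean over the truth disk equals
the declared mean exactly. Markers are cytoplasmic, so Iba1/Clec7a render
as *flat* disks at 1.2× the nucleus radius: whatever sub-region the
nuclear segmentation captures, its mean is the planted value — without
this, the segmented region's spill past the truth disk diluted marker
means by ~5% and biased the recovered gradient. Nucleus centers keep
≥ 1.32×(r_i+r_j) separation so neighbouring somata stay off each other's
nuclei; plaques are unions of 3–6 jittered disks (irregular outline, exact
truth mask). Truth distances are exact center-to-nearest-plaque-pixel
distances (KD-tree; verified against a brute-force scan). With the default
field, baseline 200 and slope −1.5/µm keep planted Clec7a means positive;
a steeper gradient can hit the intensity floor, which clips the truth
table and warns.

What the scenes do *not* model: optics (PSF, depth attenuation), irregular
nucleus shapes, intensity bleed-through between channels, spatially
correlated noise. Passing the recovery suite therefore shows the pipeline
chain is correct and unbiased under its own assumptions, not that it
handles every real-tissue artifact.

**Axon tables.** Inner diameter lognormal (median 0.8 µm, log-sd 0.3);
g-ratio truncated normal in (0.05, 0.99) around the group mean (defaults
0.75 vs 0.85, sd 0.05); areas emitted consistently with the sampled
diameters, 3 animals × 20 axons per group as in the EM protocol.

**Bead counts.** Zero-inflated Poisson: structural zero with probability
0.3, else Poisson with the group rate (defaults 3.0 vs 1.5), 4–5 fields ×
20 cells per animal.

**Composition.** Multinomial counts (1000 cells/sample, 3 samples/group)
from per-genotype probability vectors.

**DEG tables.** Significant entries draw log2FC from U(0.3, 3) and FDR
from U(0, 0.009); decoys fail exactly one filter; two boundary decoys sit
exactly at log2FC = 0.25 and FDR = 0.01 to pin the strict inequalities.
Set sizes and intersection are exact by construction.

## Problem sizes in tests and the acceptance script

Ground-truth recovery runs 20 scenes (plus noiseless twins for the plaque
count); the Kruskal–Wallis power check 200 tables; ANOVA power 200 and the
null 500–1000 simulations; KL calibration 100 runs of 200 cells with 100
permutations each. These sizes put Monte-Carlo standard errors well inside
the asserted margins (e.g. a 0.05-level rejection rate estimated from 1000
draws has s.e. ≈ 0.007 against a ±0.02 band) while the whole suite stays
in a few CPU-minutes.

## Known limitations

- The imaging operators follow the published parameter values but are not
  bit-compatible with any specific ImageJ macro (different FFT windowing,
  rolling-ball shrink factors, histogram conventions).
- Positivity calling assumes each image contains both positive and
  negative cells; an image of only positives will still split them.
- The KL statistic depends on the supplied embedding; no embedding is
  computed here.
- Histological metrics take counts/ROI means as inputs; detecting those
  events in images is the caller's concern beyond the provided pipelines.
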