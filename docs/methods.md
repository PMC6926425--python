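# Methods

## Viability normalization

Each plate is treated as its own normalization unit, matching per-plate
luminescence assay practice and absorbing plate-to-plate gain differences.
The background is the arithmetic mean of the plate's designated blank wells
(an explicit override is accepted; with neither, the background falls back
to 0 with a logged warning — the package does not guess at instrument
offsets). Relative viability of well *i* is

    v_i = max(0, raw_i − bg) / mean_{j ∈ ref}(raw_j − bg)

with the reference set either mock (untransfected) or scrambled
(non-targeting) wells, selectable per analysis; both columns are emitted
when both control types exist. Negative background-subtracted values are
clamped to 0 and flagged `clamped_negative` rather than propagated:
viability is non-negative by definition, and the flag preserves the
information for QC. Consequences that are asserted as invariants: reference
wells average to exactly 1, and the transform is invariant to any global
positive rescaling of the raw values. Wells present in the plate map but
missing from the readouts are dropped (failed wells are a fact of plate
work), while readout wells absent from the plate map are a hard schema
error. Replicate summaries use the sample (n−1) standard deviation, which
is the right choice for the small control counts typical of these plates;
sd is undefined (NaN) at n = 1.

## LOD scoring and hit calling

Both control sets are modelled as normal distributions fitted by sample
mean and sample sd (minimum three finite values each; zero spread is
rejected as degenerate). The default score is the log likelihood ratio of
normal densities,

    LOD(x) = log10[ φ(x; μ_pos, σ_pos) / φ(x; μ_neg, σ_neg) ],

which for equal variances reduces to the closed form
[(x−μ_neg)² − (x−μ_pos)²] / (2σ² ln 10) — linear in x, antisymmetric under
swapping the control models, and exactly 3 where the density ratio is
1,000. A second variant scores lower-tail cumulative probabilities instead
of densities (`cdf_tail`); it is monotone in x like the density form but
saturates at 0 for clearly viable values rather than going negative. The
density form is the default because the likelihood-ratio definition of the
score is stated in terms of the probability of linkage to each control
phenotype, and because its algebraic properties make calibration checks
exact. Probabilities are floored at 1e-300 before the ratio so extreme
viabilities produce large finite scores instead of ±inf; the floor cannot
change any ranking.

Scoring operates on per-guide mean normalized viability by default (one
score per gene knockout); scoring individual wells is possible by passing
per-well values. The hit threshold is inclusive: `lod >= 3`.

Screen QC fails a run when the standardized control separation
(μ_neg − μ_pos)/pooled-sd falls below 3, or when either control sample's
Kolmogorov–Smirnov p-value against its fitted normal drops below 0.01. The
KS test uses estimated parameters without a Lilliefors correction, which
makes the p-values conservative (the false-alarm rate observed in the
acceptance run is ≈ 0 at nominal 5 %); they are reported as a diagnostic,
not as a formal test, and that caveat is deliberate. Replicate concordance
reports Pearson and Spearman correlations over guides shared between two
replicates (minimum three).

No multiple-testing correction is applied across genes: the LOD ≥ 3 rule is
the screen's sole significance criterion, and the synthetic-screen false
positive rate under that rule is measured directly instead.

## Image phenotyping

Nuclear segmentation: median filter (disk radius 2 px) → Otsu global
threshold → hole filling → watershed on the negated Euclidean distance
transform. Watershed seeds are local maxima of the lightly smoothed
distance map (Gaussian σ = 0.5, minimum seed separation 5 px); the raster
scan order of the peak finder makes tie-breaking deterministic (lower row,
then column, wins). Objects below 40 px, above an optional maximum, or
touching the image border are discarded and labels renumbered contiguously.
Otsu was fixed as the "automated threshold" because it is the standard
default of the CellProfiler/KNIME era of high-content workflows and is
invariant to affine intensity rescaling, which the tests assert. The
smoothing and seed-separation defaults were chosen on the synthetic image
scale (nuclei of radius ~14 px in 512×512 fields): heavier smoothing merges
seeds of unequal touching pairs, lighter seeding over-splits noisy masks.

Per-nucleus measurements are the mean and total intensity in each channel
and the pixel area (converted to μm² when the pixel size is known).
Intensities are not background-subtracted before averaging by default.

Per-cell punctate (Golgi-like) quantification: cell regions are a
nearest-nucleus (Voronoi-like) assignment of background pixels clipped at
25 px from any nucleus — dilation without region overlap. The signal
channel is white top-hat filtered (disk radius 6 px, larger than a
punctum, smaller than a cell) to remove local background, Otsu-thresholded
into fragment cores, and the cores are dilated by 3 px so the dim Gaussian
tails of puncta are included; each cell's fragment pixels are summed in the
original channel and corrected by fragment-pixel-count × the median
intensity of pixels outside all cell regions. The median (not mean) makes
the background estimate robust to stray fragments outside cells. The
correction makes the measurement exactly invariant to a uniform added
background, which the tests assert; total recovered punctum intensity is
within a few percent of the generated ground truth.

Object QC is a deterministic surrogate for interactive curation of
high-content images, not a reproduction of it: rules exclude objects whose
mean nuclear intensity exceeds a chosen percentile of the per-object means
(mitotic/condensed chromatin), objects below a solidity minimum (debris,
out-of-focus blobs) and border objects, each exclusion listed with its
reason.

Group comparisons are two-sided Mann–Whitney U or two-sample
Kolmogorov–Smirnov tests (scipy), with the effect size reported as the
target median divided by the scrambled median.

## Protein turnover and targetability

Exponentially degraded (ED) proteins follow one-state decay with half-life
ln 2/k. Non-exponentially degraded (NED) proteins are modelled as a
two-pool mixture R(t) = α·e^(−k_fast·t) + (1−α)·e^(−k_slow·t) with
k_fast ≥ k_slow; R decreases strictly from 1 to 0, so R(t) = 1/2 has a
unique root, bracketed between the pure-fast and pure-slow half-lives and
solved by a bracketing root finder to well below the 1e-6 h contract. The
two-pool mixture is a declared parameterization choice: the module accepts
precomputed per-protein parameters rather than fitting pulse-chase data,
and results against any particular measured turnover dataset may differ
from the synthetic summaries computed here. Classification is strict:
half-life > 120 h ⇒ hard to target; exactly 120 h remains targetable. The
120-h threshold reflects the ~3–5 day window of an arrayed screen: a
protein with a longer half-life retains more than half its initial level
when the phenotype is read.

## Synthetic data: what it emulates and what it does not

Plates: raw luminescence is blank_mean + (mock_mean − blank_mean) × effect
× log-normal noise with coefficient of variation 5 % (multiplicative,
because luminescence is positive and assay noise scales with signal; blank
wells read the blank mean exactly, as the noise term multiplies the signal
component). Default effects: scrambled 1.0; positive control 0.15,
i.e. an 85 % viability loss on the scale of an essential-gene knockout;
planted lethal genes 0.2. The default screen is 45 genes (40 neutral, 5
shared lethal) plus optional line-specific dependencies, two replicate
plates per cell line on a 96-well layout with mock, blank, scrambled and
positive-control wells. Every generator takes an explicit seed and owns a
private random stream; reruns are bit-identical.

Images: nuclei are anti-aliased disks (radius ~ N(14, 2) px) placed without
overlap, with a configurable fraction placed as touching pairs at center
distance 0.8×(r₁+r₂); the signal channel is either a nuclear marker at a
set level or perinuclear Gaussian puncta of known integrated intensity;
Gaussian and optional Poisson noise are applied last. Ground-truth label
maps and per-object tables are emitted with every field.

What the generators do not emulate: spatial plate effects (edge
evaporation, gradients), transfection-efficiency kinetics, cell-growth
dynamics, non-disk nuclear shapes, illumination inhomogeneity, out-of-focus
blur, or real antibody background structure. Tests passing on these data
therefore demonstrate the correctness of the computations and their
calibration under the stated noise model — not robustness to every artifact
of real plates and microscopes. Spatial plate-effect correction (B-scores
and the like) is deliberately out of scope.

## Problem sizes and numerical choices

The test suite and the acceptance script use 200 seeded screens for hit
recovery, 100 seeds for control-QC calibration, 200 objects per arm for
phenotype comparisons, 1,000 null permutations for the type-I check,
ten 512×512 fields for segmentation recall, and 1,000-protein turnover
tables — sizes at which every stochastic bound being checked has
comfortable margin. Fixed tolerances: LOD closed-form agreement 1e-9;
half-life solver 1e-6 h against its contract and 0.01 h against a dense
grid oracle; normalization reference mean exact to 1e-12. Degenerate
inputs fail loudly (constant images, zero-spread controls, empty tables)
rather than returning defaults.
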