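# Methods

This note documents the models, parameter choices and numerical decisions
behind `embryoexpress`, and what the synthetic-data generators do and do not
emulate.

## Coordinate conventions

All modules share one normalized embryo frame: AP (anterior–posterior)
fraction 0 = anterior, 1 = posterior; DV (dorsoventral) fraction 0 = dorsal,
1 = ventral; images are row-major with row 0 at the top, so a horizontal
embryo with anterior on the left has AP increasing with column and DV with
row. A frame's `rotation_angle` is the displayed-counter-clockwise angle of
the AP axis from the image x-axis, in (−90°, 90°]; the rotation *applied* to
level the embryo is its negative. The 180° anterior/posterior ambiguity of
an axis cannot be resolved from a mask, so `anterior_end` must come from
acquisition metadata or generator truth; frames default to `unresolved` and
AP-directional operations refuse to run until it is set, rather than
guessing.

## Sequence library simulators

**Mutant libraries.** The error-prone-PCR "~0.5 % per molecule" regime is
modelled as an independent per-base substitution probability (default
0.005/base); each mutated base goes to one of the three other bases
uniformly. This reproduces the observed 1–5 substitutions on 290–484 bp
enhancers (Binomial(L, r) counts). Indels are not simulated: none are
analysed downstream. Every variant carries its mutation list
(position, ref, alt), and applying the list to the reference must
reconstruct the variant — an invariant the tests check exhaustively.

**Random libraries.** Fixed-length random ACGT sequences (default design
~180 bp) with an optional embedded motif. "Approximately at the centre" is
made deterministic as offset ⌊(L−m)/2⌋; `uniform` and fixed-offset policies
exist for other designs. Uniqueness is enforced by rejection-resampling on
collision. Library summaries report the mean as total mutations / lines
(e.g. 505/91 ≈ 5.5).

## Embryo image generator

A stage-5-like embryo is an ellipse (defaults: semi-axes 300 × 120 px, i.e.
a ~600 px egg length) with `count` nuclei packed by dart throwing (uniform
proposals, minimum centre separation). Defaults are 500 nuclei of radius
4 px at ≥10 px separation — a surface density in the spirit of the
syncytial blastoderm while staying safely below the random-sequential-
adsorption jamming limit, so packing always terminates; the packing raises
a generation error rather than looping when a requested density is
infeasible. Channel 1 renders hard-edged nucleus disks (amplitude 8000 a.u.)
on a faint cytoplasmic plateau (600 a.u.) so the full embryo footprint is
visible, as in DAPI max-projections. Channel 2 evaluates the analytic
pattern at each pixel's (AP, DV) and restricts it to nucleus footprints
(nuclear reporter readout; `reporter_support="embryo"` paints the whole
footprint instead). Gaussian noise (clipped to the valid range) and an
optional linear shading ramp are added before quantization to uint16.

Pattern primitives are additive with Gaussian cross-sections: AP stripes
and DV bands with free centre/σ; a lateral domain = two symmetric DV bands
(centres 0.25/0.75, σ 0.08); a ventral domain = band at DV 0.85 (σ 0.07);
a posterior cap = logistic step in AP at 0.85 (softness 0.03); and a
uniform term. Ground truth records the frame, each nucleus's centroid,
(AP, DV) and the mean of the noiseless pattern over its pixel footprint, the
pattern value at each germ-layer ROI centre, and each stripe primitive's
centre/σ/FWHM.

**What the generator does not emulate:** optical PSFs and 3-D structure,
stage-dependent morphogenesis, nuclear-density gradients, autofluorescence
texture, staining variability between embryos, and partially overlapping
nuclei in projections. Passing tests therefore demonstrate correctness of
the measurement pipeline on images whose geometry and noise are known, not
robustness to every real-microscopy artefact.

## Masking, axis fit, segmentation

The embryo mask comes from Otsu thresholding the lightly smoothed (σ = 2 px)
log-intensity nuclear channel — in log space the background/embryo gap
dominates the cytoplasm/nuclei gap — followed by a half-height refinement in
linear space (background median vs. foreground lower quartile, i.e. the
cytoplasmic plateau) that undoes the blur-induced edge shift, then closing
(disk radius 10), hole filling and keeping the single largest component
(stray debris is thereby excluded). Our Otsu returns the *upper edge* of the
optimal histogram bin: the conventional bin-centre return mis-splits spiky
discrete histograms where a class value sits inside the argmax bin.

The AP axis orientation is the moment-ellipse (principal-axes) orientation,
which is sub-0.1° accurate on pixelized masks; the maximum-Feret-diameter
direction — computed exactly from the convex hull of pixel corners — must
agree within 5° and provides the egg length L. Egg height is the mask
extent perpendicular to the axis. Masks with axis ratio < 1.1 are rejected
as orientation-ambiguous.

Nuclei are segmented by Otsu inside the mask, removal of objects below
`min_area` (default 4 px², the 2-D mapping of a "volume > 3" filter), and a
watershed on the negated distance transform seeded by its local maxima at a
minimum separation of one median nucleus radius. A single unified
segmentation path deliberately replaces the per-enhancer tool mixture used
in practice.

## AP profiles

For each AP pixel position (one bin per pixel of egg length), reporter
pixels whose DV lies within the central band (default 30 % of embryo
height) ∩ mask are averaged. Smoothing uses a Gaussian of σ = 0.01 egg
lengths (unstated in the original procedure; chosen at the scale of one
internucleus spacing so single-nucleus shot noise is averaged without
blurring stripe shape), then linear interpolation to 1000 samples on [0,1].
Normalization is `(I − Q10)/(Q50 − Q10)` with both quantiles (linear
interpolation between order statistics) taken from the posterior 20 % of
the profile — the exact arithmetic is a design choice: it is affine
invariant and pins the tail background to 0 and tail median to 1. The
order is smooth → interpolate → normalize, recorded in each profile's
provenance. A numerically flat tail raises a degenerate-normalization
error. Bootstrap bands resample *embryos* (the replicate unit), 1000
replicates, pointwise 95 % quantile envelopes. With ~10 embryos per line
the percentile bootstrap undercovers slightly (≈90 % pointwise); the
coverage study in the acceptance script uses 20 embryos per line, inside
the 6–27 embryos-per-line range typical of such screens.

## Stripe calling and width

Nuclei are binned by AP (default width 0.05; bins tile [0,1] half-open,
out-of-range positions clamp to edge bins). Each bin's DV profile is a
Nadaraya–Watson kernel estimate (grid 0.01, σ 0.02) of mean nuclear
fluorescence; grid points beyond ~3σ of every nucleus are undefined. Peaks
need prominence ≥ 25 % of the bin's profile range (profiles flat to
numerical precision carry none); the half-maximum interval is measured
relative to the bin's local baseline (profile minimum). Peaks link across
adjacent bins by greedy nearest-DV matching within a 0.05 jump, *or* when a
peak falls inside the previous bin's half-max interval — broad stripes have
plateau peaks that wander more than any fixed jump. Traces spanning < 60 %
of non-empty bins are dropped.

Membership per bin is positional (DV inside the half-max interval) with a
default-on intensity filter: a member must itself reach the half-maximum
fluorescence level. This is the automated counterpart of the manual
curation such pipelines require — with purely positional membership, a
stripe oblique to the AP axis systematically sweeps dim off-stripe nuclei
into the corners of axis-aligned bins and the width statistic inflates.
Explicit include/exclude id lists override everything and are honoured
verbatim; the positional-only rule is available via
`intensity_filter=False`.

The midline is fitted per AP segment (default length 0.40 egg lengths) by
orthogonal least squares (principal axis of the member centroids), so the
per-segment width — the largest perpendicular spread between member
centres — is measured truly perpendicular to the stripe and is invariant
under rigid rotations of the coordinates. The long default segment keeps
enough members (~100 at typical densities) for this extreme-value statistic
to stabilise; shorten it for visibly curved stripes. Overall width is the
arithmetic mean of segment widths; segments with fewer than two members
contribute none, and a stripe whose members share one AP position is a
degenerate-geometry error. The half-maximum interval is interpreted as a
DV interval within each AP bin (the peak lives in the bin's DV profile);
this is flagged here as the single supported reading.

## Germ-layer ROIs and statistics

Circular ROIs of constant radius (default 15 px — "constant size" with no
stated value) at fixed normalized positions: ectoderm (AP 0.5, DV 0.3),
mesoderm (AP 0.5, DV 0.85), endoderm (AP 0.92, DV 0.5); all configurable,
and an ROI leaving the mask is a placement error, never silently clipped.
The per-line test is Student's pooled-variance two-tailed t-test (the
classical reading of "two-tailed t test"; Welch via flag). Two identical
constant samples give (t, p) = (0, 1) by convention. Calls: `up`/`down`
when p < α (default 0.05) by sign of the mean difference, else
`unchanged`. No multiple-testing correction by default, mirroring per-line
p < 0.05 usage; Benjamini–Hochberg is available as an extra column.

## Motif information content and scanning

Information content is the Kullback–Leibler divergence of the PWM from the
background, `I = Σᵢ Σₙ pᵢₙ log₂(pᵢₙ/bₙ)` bits; `2^−I` approximates the
per-position chance-hit probability (exact for quasi-Boolean motifs, where
the admissible-word probability is exactly 2^−I). Count matrices get an
additive per-cell pseudocount (default 0.01); the default background is
uniform. The ECDF of expected frequencies over a collection is the step
function k/N at the k-th sorted frequency.

Scanning scores every window with the log₂-odds sum on both strands
(reverse-complement PWM on the forward sequence; coordinates always
forward-strand, half-open). P-values are exact at the chosen granularity:
per-column scores are shifted and discretized so the attainable range spans
1000 integer bins (configurable), the null distribution of the integer
total is built by position-wise convolution under the background, and
windows are scored *in the same integer space*, so the lookup is exact —
the classic FIMO construction re-implemented so no external binary is
needed. Discretization can move a word by at most half a bin per column
(L/2 bins total), the bound the oracle tests use. Agreement with exhaustive
4^L enumeration is the contract; agreement with any external scanner is
not. Windows containing non-ACGT letters are voided; overlapping hits are
all reported; the top-score filter keeps ⌈0.30·n⌉ hits per motif across
all sequences (the per-motif reading of an ambiguous "top 30 %" rule;
configurable). For motifs with lumpy (near-degenerate) score
distributions the exact p-value is conservative — the realized hit rate at
threshold t can be well below t because no achievable tail value is close
to t; the calibration study therefore uses a generic (gamma-count) motif.

## Pipeline and reproducibility

A run config (YAML or dict) holds geometry, pattern, effect size, noise,
ROI and test parameters; unknown keys are rejected by name. One run seed
fans out to per-embryo child seeds through `SeedSequence.spawn`, so any
embryo regenerates in isolation and two identically configured runs are
byte-identical (config hash = SHA-256 of the canonical JSON). Per-embryo
failures are recorded and skipped; a run only fails when a group has fewer
than two usable embryos. Reports are written as mirrored JSON + CSV with a
schema version.

## Problem sizes in the acceptance script

The script uses 10⁴ lines for PCR calibration, 9 rotations for axis
recovery, 3 stripe positions × 10 embryos at 10 % noise for profile
recovery, 200 lines × 20 embryos × 1000 bootstrap replicates for coverage,
5000-nucleus tables for stripe widths, 10⁴ null replicates for t-test
calibration, full 4^8 enumeration for the motif oracle, and 10⁶ bp for
scan calibration — sizes at which the Monte-Carlo error of each quantity is
small against its tolerance.

## Known limitations

* The generator's simplifications listed above; in particular, zero-noise
  ground-truth agreement is exact only because rendered and measured
  nucleus footprints coincide.
* Percentile-bootstrap undercoverage at small embryo counts is inherited
  from the method, not corrected (no BCa).
* The stripe-width statistic (max spread) is extreme-value based and noisy
  at low nucleus density; defaults assume a few thousand nuclei.
* Exact p-values are conservative for degenerate PWMs (see above).
* Scanning assumes a 0-order background; dinucleotide models are out of
  scope.
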