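# embryoexpress

Quantification of reporter expression in *Drosophila* embryo images, and
motif-potential analysis of enhancer sequence libraries.

Enhancer-mutagenesis reporter screens ask how point mutations in a
cis-regulatory element change the expression pattern it drives. The assay
images fixed embryos carrying `enhancer -> hsp70 -> lacZ` constructs
(two channels: nuclear stain + reporter) and, on the sequence side, builds
error-prone-PCR variant libraries and random-sequence libraries with
embedded transcription-factor motifs. `embryoexpress` implements the desk
half of such a screen as a tested, reusable Python library:

* **Synthetic data with ground truth** — PCR mutagenesis libraries
  (independent per-base substitution at rate *r*, so mutation counts are
  Binomial(L, r)), random oligo libraries with a motif planted at a known
  offset, and rendered two-channel embryo max-projections with analytic
  expression patterns (AP stripes, DV bands, lateral/ventral/posterior
  domains) and per-nucleus truth.
* **Image quantification** — embryo masking; AP-axis fitting from the
  fitted-ellipse orientation cross-checked against the maximum Feret
  diameter; normalized (AP, DV) ∈ [0,1]² coordinates; Otsu + watershed
  nucleus segmentation; per-nucleus reporter means.
* **AP expression profiles** — mean intensity over the central 30 % band of
  embryo height per AP position, Gaussian smoothing, resampling to a fixed
  grid, and normalization `(I − Q10)/(Q50 − Q10)` against the 10 %/50 %
  quantiles of the posterior 20 % of egg length; per-line bootstrap bands
  (1000 replicates, 95 %).
* **Stripe calling** — bin nuclei by AP, kernel-smoothed DV fluorescence
  profiles per bin, peak detection and cross-bin linking, half-maximum
  membership, piecewise-linear midline fit, width measured perpendicular to
  each segment as the largest spread between member nucleus centres.
* **Germ-layer readout** — circular ROIs of constant size at lateral
  (ectoderm), ventral (mesoderm) and posterior (endoderm) positions;
  per-line two-tailed Student t-tests and up/down/unchanged calls.
* **Motif tools** — PWM I/O (MEME minimal, count TSV), Kullback–Leibler
  information content `I = Σᵢ Σₙ pᵢₙ log₂(pᵢₙ/bₙ)` (bits), the `2^−I`
  expected chance-hit frequency and its ECDF over a motif collection, and
  FIMO-style log₂-odds scanning with **exact** p-values from a dynamic
  program over discretized column scores (default threshold p ≤ 0.001,
  top-30 %-score filter).

## Worked example

```python
from embryoexpress import (EmbryoGeometry, PatternSpec, fit_embryo_frame,
                           mask_embryo, measure_regions, render_embryo)
from embryoexpress.patterns import ventral_domain

geometry = EmbryoGeometry(semi_major=300, semi_minor=120, rotation_angle=15.0)
pattern = PatternSpec([ventral_domain(400.0)], baseline=30.0)
image, truth = render_embryo(geometry, pattern, noise=20.0, seed=4)

mask = mask_embryo(image)
frame = fit_embryo_frame(mask, anterior_end="left")
triplet = measure_regions(image, frame, mask=mask.mask)
print(frame.rotation_angle, triplet.ectoderm, triplet.mesoderm)
```

Running `python examples/quantify_embryo_expression.py` (this pipeline plus
nucleus segmentation) prints:

```
embryo mask area:    113075 px^2
recovered rotation:  +14.97 deg (true +15.00)
nuclei segmented:    500 (true 500)
ectoderm ROI mean:       15.9 a.u.
mesoderm ROI mean:       86.1 a.u.
endoderm ROI mean:       11.9 a.u.
```

The embryo was rendered at 15° with a ventral (presumptive-mesoderm)
pattern: the fitted axis recovers the rotation to 0.03°, all 500 nuclei are
found, and the mesoderm ROI reads ~5-fold above the other germ-layer
proxies — the quantitative signature of a ventrally restricted pattern.
`examples/` contains one short script per capability (libraries, profiles,
stripes, motifs, full pipeline).

A thin CLI mirrors the main entry points
(`embryoexpress simulate-library|simulate-embryos|segment|profile|stripes|motifs|run`);
exit codes are 0/1/2 for ok / domain error / config error.

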