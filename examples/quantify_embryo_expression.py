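"""Quantify germ-layer reporter expression in a synthetic embryo.

Renders a two-channel stage-5-like embryo whose reporter is driven by a
ventral (presumptive mesoderm) pattern, then runs the measurement pipeline:
mask the embryo, fit the AP axis, segment nuclei, and read out the three
germ-layer proxy ROIs.
"""

from embryoexpress import (EmbryoGeometry, PatternSpec, fit_embryo_frame,
                           mask_embryo, measure_nuclei, measure_regions,
                           render_embryo, segment_nuclei)
from embryoexpress.patterns import ventral_domain

geometry = EmbryoGeometry(semi_major=300, semi_minor=120, rotation_angle=15.0)
pattern = PatternSpec([ventral_domain(400.0)], baseline=30.0)
image, truth = render_embryo(geometry, pattern, noise=20.0, seed=4)

mask = mask_embryo(image)
frame = fit_embryo_frame(mask, anterior_end="left")
segmentation = segment_nuclei(image.nuclear, mask, frame=frame)
nuclei = measure_nuclei(segmentation, image.reporter)
triplet = measure_regions(image, frame, mask=mask.mask)

print(f"embryo mask area:    {mask.area} px^2")
print(f"recovered rotation:  {frame.rotation_angle:+.2f} deg (true +15.00)")
print(f"nuclei segmented:    {len(nuclei)} (true {len(truth.nuclei)})")
print(f"ectoderm ROI mean:   {triplet.ectoderm:8.1f} a.u.")
print(f"mesoderm ROI mean:   {triplet.mesoderm:8.1f} a.u.")
print(f"endoderm ROI mean:   {triplet.endoderm:8.1f} a.u.")
print()
print("The ventral pattern shows up as a mesoderm ROI far above the other")
print("two regions; with a uniform pattern all three would be equal.")
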