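"""Synthetic two-channel embryo renderer with exact ground truth.

The generator draws a stage-5-like embryo as an ellipse (long axis = AP),
packs non-overlapping nuclei inside it, and renders

* channel 1 (nuclear stain): nucleus disks on a faint cytoplasmic plateau so
  the whole embryo footprint is visible, as in real DAPI max-projections;
* channel 2 (reporter): the analytic expression pattern evaluated at each
  pixel's normalized (AP, DV) coordinates, restricted to nuclear footprints
  (reporter signal is nuclear in the assays being emulated), plus optional
  Gaussian noise and an optional linear shading gradient.

Every rendered nucleus, region and stripe carries analytically derived ground
truth, so downstream measurements can be validated against known values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .core import EmbryoImage, NucleusRecord
from .errors import GenerationError, InputError
from .frames import EmbryoFrame
from .patterns import PatternSpec, pattern_value

GAUSSIAN_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: default normalized (AP, DV) centres of the germ-layer proxy regions:
#: ectoderm = lateral, mesoderm = ventral, endoderm = posterior.
DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "ectoderm": (0.50, 0.30),
    "mesoderm": (0.50, 0.85),
    "endoderm": (0.92, 0.50),
}


@dataclass
class EmbryoGeometry:
    """Elliptical embryo geometry in pixels.

    ``rotation_angle`` is the displayed-CCW angle of the AP axis from the
    image x-axis, in (-90, 90]; ``center`` defaults to the image centre.
    """

    semi_major: float = 300.0
    semi_minor: float = 120.0
    center: tuple[float, float] | None = None
    rotation_angle: float = 0.0
    anterior_end: str = "left"

    def __post_init__(self):
        if not self.semi_major > self.semi_minor > 0:
            raise InputError("require semi_major > semi_minor > 0")
        if not -90.0 < self.rotation_angle <= 90.0:
            raise InputError("rotation_angle must lie in (-90, 90]")
        if self.anterior_end not in ("left", "right"):
            raise InputError("anterior_end must be 'left' or 'right'")

    def image_shape(self, margin: int = 25) -> tuple[int, int]:
        t = np.deg2rad(self.rotation_angle)
        a, b = self.semi_major, self.semi_minor
        half_w = np.sqrt((a * np.cos(t)) ** 2 + (b * np.sin(t)) ** 2)
        half_h = np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
        return (int(np.ceil(2 * (half_h + margin))),
                int(np.ceil(2 * (half_w + margin))))

    def frame(self, shape: tuple[int, int] | None = None) -> EmbryoFrame:
        if self.center is not None:
            center = self.center
        else:
            shape = shape or self.image_shape()
            center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        return EmbryoFrame(
            center=center,
            rotation_angle=self.rotation_angle,
            egg_length=2.0 * self.semi_major,
            egg_height=2.0 * self.semi_minor,
            anterior_end=self.anterior_end,
            ellipse_axes=(self.semi_major, self.semi_minor),
        )


@dataclass
class GroundTruth:
    """Analytic truth emitted alongside a rendered embryo."""

    geometry: EmbryoGeometry
    frame: EmbryoFrame
    nuclei: pd.DataFrame            # id, row, col, ap, dv, true_mean
    region_means: dict[str, float]
    stripes: list[dict]
    labels: np.ndarray = field(repr=False, default=None)
    seed: int | None = None


def ellipse_mask(geometry: EmbryoGeometry,
                 shape: tuple[int, int] | None = None) -> np.ndarray:
    """Exact (analytic) embryo footprint raster for a geometry."""
    shape = shape or geometry.image_shape()
    frame = geometry.frame(shape)
    ap, dv = frame.normalized_grid(shape)
    return (2 * (ap - 0.5)) ** 2 + (2 * (dv - 0.5)) ** 2 <= 1.0


def _place_nuclei(frame: EmbryoFrame, count: int, radius: float,
                  min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement of nucleus centres inside the ellipse."""
    a = frame.egg_length / 2.0
    b = frame.egg_height / 2.0
    # shrink so whole disks stay inside the ellipse
    fa = (a - radius - 1.0) / a
    fb = (b - radius - 1.0) / b
    if fa <= 0 or fb <= 0:
        raise GenerationError("nucleus radius exceeds embryo size")
    placed = np.empty((count, 2))
    n_placed = 0
    max_tries = 2000 * count + 2000
    tries = 0
    min_sep2 = min_sep ** 2
    while n_placed < count:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not pack {count} nuclei at separation {min_sep} px "
                f"after {max_tries} attempts")
        # uniform in unit disk -> scale to the shrunken ellipse
        x, y = rng.uniform(-1, 1, size=2)
        if x * x + y * y > 1.0:
            continue
        ap = 0.5 + (x * fa) / 2.0
        dv = 0.5 + (y * fb) / 2.0
        r, c = frame.to_pixel(ap, dv)
        if n_placed and np.min((placed[:n_placed, 0] - r) ** 2
                               + (placed[:n_placed, 1] - c) ** 2) < min_sep2:
            continue
        placed[n_placed] = (float(r), float(c))
        n_placed += 1
    return placed


def render_embryo(geometry: EmbryoGeometry,
                  spec: PatternSpec,
                  nuclei: tuple[int, float, float] = (500, 4.0, 10.0),
                  noise: float | tuple[float, float] = 0.0,
                  seed: int = 0,
                  nuclear_amplitude: float = 8000.0,
                  interior_level: float = 600.0,
                  reporter_support: str = "nuclei",
                  shape: tuple[int, int] | None = None,
                  ) -> tuple[EmbryoImage, GroundTruth]:
    """Render a two-channel embryo image and its ground truth.

    Parameters
    ----------
    nuclei
        ``(count, radius_px, min_center_separation_px)``.
    noise
        Gaussian noise sd in a.u., or ``(sd, gradient)`` where ``gradient``
        is the peak amplitude of an additive left-to-right linear ramp on the
        reporter channel (uneven-illumination stand-in).
    reporter_support
        ``"nuclei"`` restricts reporter signal to nucleus footprints (the
        default, matching nuclear reporter readouts); ``"embryo"`` paints the
        pattern over the whole embryo footprint.
    """
    if reporter_support not in ("nuclei", "embryo"):
        raise InputError("reporter_support must be 'nuclei' or 'embryo'")
    sd, gradient = (noise if isinstance(noise, tuple) else (noise, 0.0))
    count, radius, min_sep = nuclei
    shape = shape or geometry.image_shape()
    frame = geometry.frame(shape)
    rng = np.random.default_rng(seed)

    ap_r, dv_r = frame.normalized_grid(shape)
    emb_mask = (2 * (ap_r - 0.5)) ** 2 + (2 * (dv_r - 0.5)) ** 2 <= 1.0
    pat = np.zeros(shape, dtype=float)
    pat[emb_mask] = pattern_value(spec, np.clip(ap_r[emb_mask], 0, 1),
                                  np.clip(dv_r[emb_mask], 0, 1))

    centers = _place_nuclei(frame, count, radius, min_sep, rng)
    nuclear = np.zeros(shape, dtype=float)
    nuclear[emb_mask] = interior_level
    labels = np.zeros(shape, dtype=np.int32)
    w = int(np.ceil(radius)) + 2
    for i, (r0, c0) in enumerate(centers, start=1):
        r_lo, r_hi = int(r0) - w, int(r0) + w + 1
        c_lo, c_hi = int(c0) - w, int(c0) + w + 1
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                             indexing="ij")
        dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
        inside = dist <= radius
        nuclear[r_lo:r_hi, c_lo:c_hi][inside] += nuclear_amplitude
        patch = labels[r_lo:r_hi, c_lo:c_hi]
        patch[inside & (patch == 0)] = i

    support = (labels > 0) if reporter_support == "nuclei" else emb_mask
    reporter = np.where(support, pat, 0.0)
    if gradient:
        ramp = gradient * (np.arange(shape[1]) / max(shape[1] - 1, 1))
        reporter = reporter + ramp[None, :]
    if sd > 0:
        nuclear = nuclear + rng.normal(0.0, sd, shape)
        reporter = reporter + rng.normal(0.0, sd, shape)

    def _quantize(x):
        return np.clip(np.rint(x), 0, 65535).astype(np.uint16)

    image = EmbryoImage(nuclear=_quantize(nuclear),
                        reporter=_quantize(reporter),
                        metadata={"seed": seed,
                                  "rotation_angle": geometry.rotation_angle,
                                  "anterior_end": geometry.anterior_end})

    ids = np.arange(1, len(centers) + 1)
    true_means = ndi.mean(pat, labels=labels, index=ids)
    ap_c, dv_c = frame.to_normalized(centers[:, 0], centers[:, 1])
    truth_nuclei = pd.DataFrame({
        "id": ids, "row": centers[:, 0], "col": centers[:, 1],
        "ap": ap_c, "dv": dv_c, "true_mean": true_means,
    })
    region_means = {name: float(pattern_value(spec, apdv[0], apdv[1]))
                    for name, apdv in DEFAULT_REGIONS.items()}
    stripes = []
    for p in spec.primitives:
        if p.kind == "ap_stripe":
            stripes.append({"axis": "ap", "center": p.center,
                            "sigma": p.sigma, "fwhm": GAUSSIAN_FWHM * p.sigma,
                            "amplitude": p.amplitude})
        elif p.kind == "dv_band":
            stripes.append({"axis": "dv", "center": p.center,
                            "sigma": p.sigma, "fwhm": GAUSSIAN_FWHM * p.sigma,
                            "amplitude": p.amplitude})
    truth = GroundTruth(geometry=geometry, frame=frame, nuclei=truth_nuclei,
                        region_means=region_means, stripes=stripes,
                        labels=labels, seed=seed)
    return image, truth


def simulate_stripe_nuclei(n_nuclei: int = 5000,
                           stripe_centers: tuple[float, ...] = (0.6,),
                           stripe_width: float = 0.10,
                           intensity_in: float = 1000.0,
                           intensity_out: float = 100.0,
                           noise_sd: float = 0.0,
                           ap_range: tuple[float, float] = (0.0, 1.0),
                           rotation_deg: float = 0.0,
                           image_size: tuple[int, int] = (500, 1000),
                           seed: int = 0,
                           ) -> tuple[list[NucleusRecord], dict]:
    """Scatter nuclei over the normalized frame with bright DV stripes.

    Each stripe is a hard band of total DV width ``stripe_width`` centred at
    the given DV positions, spanning ``ap_range`` in AP. Nuclei inside a band
    get ``intensity_in`` (plus noise), others ``intensity_out``. With
    ``rotation_deg`` the whole (AP, DV) point cloud is rigidly rotated about
    (0.5, 0.5), which shears the stripes away from the AP axis.

    Returns the nucleus records (reporter mean in ``mean_ch2``) and a truth
    dict with per-stripe centers, width and member ids.
    """
    rng = np.random.default_rng(seed)
    ap = rng.uniform(0.0, 1.0, n_nuclei)
    dv = rng.uniform(0.0, 1.0, n_nuclei)
    inside = np.zeros(n_nuclei, dtype=bool)
    for c in stripe_centers:
        inside |= ((np.abs(dv - c) <= stripe_width / 2.0)
                   & (ap >= ap_range[0]) & (ap <= ap_range[1]))
    intensity = np.where(inside, intensity_in, intensity_out).astype(float)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, n_nuclei)

    if rotation_deg:
        t = np.deg2rad(rotation_deg)
        x, y = ap - 0.5, dv - 0.5
        ap = 0.5 + x * np.cos(t) - y * np.sin(t)
        dv = 0.5 + x * np.sin(t) + y * np.cos(t)

    h, wpx = image_size
    records = [
        NucleusRecord(id=i + 1, row=float(dv[i] * (h - 1)),
                      col=float(ap[i] * (wpx - 1)), area=30.0,
                      ap=float(ap[i]), dv=float(dv[i]),
                      mean_ch1=5000.0, mean_ch2=float(intensity[i]))
        for i in range(n_nuclei)
    ]
    truth = {
        "stripe_centers": list(stripe_centers),
        "stripe_width": stripe_width,
        "rotation_deg": rotation_deg,
        "members": {c: (np.nonzero(inside)[0] + 1).tolist()
                    for c in stripe_centers},
        "seed": seed,
    }
    return records, truth


def write_embryo(image: EmbryoImage, truth: GroundTruth,
                 outdir: str | Path, stem: str = "embryo") -> dict:
    """Write TIFF + PNG preview + ground-truth JSON/CSV; returns paths."""
    from matplotlib import pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tif = image.to_tiff(outdir / f"{stem}.tif")
    png = outdir / f"{stem}.png"
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, chan, title in zip(axes, (image.nuclear, image.reporter),
                               ("nuclear", "reporter")):
        ax.imshow(chan, cmap="gray")
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    csv = outdir / f"{stem}_nuclei.csv"
    truth.nuclei.to_csv(csv, index=False)
    js = outdir / f"{stem}_truth.json"
    with open(js, "w") as fh:
        json.dump({
            "geometry": {
                "semi_major": truth.geometry.semi_major,
                "semi_minor": truth.geometry.semi_minor,
                "rotation_angle": truth.geometry.rotation_angle,
                "anterior_end": truth.geometry.anterior_end,
            },
            "region_means": truth.region_means,
            "stripes": truth.stripes,
            "seed": truth.seed,
        }, fh, indent=1)
    return {"tiff": tif, "png": png, "nuclei_csv": csv, "truth_json": js}
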