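"""Embryo masking, axis fitting and nucleus segmentation.

The pipeline mirrors the standard fixed-embryo workflow: build a foreground
mask for the whole embryo, fit its long (AP) axis from the maximum Feret
diameter (cross-checked against the moment-ellipse orientation), then segment
nuclei in the nuclear-stain channel by automated (Otsu) thresholding with a
distance-transform watershed to split touching nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import EmbryoImage, NucleusRecord
from .errors import InputError, NoEmbryoError, OrientationError
from .frames import EmbryoFrame


@dataclass
class EmbryoMask:
    """Binary embryo-foreground raster (one connected component, holes filled)."""

    mask: np.ndarray
    area: int


def _as_nuclear(image) -> np.ndarray:
    if isinstance(image, EmbryoImage):
        return np.asarray(image.nuclear, dtype=float)
    return np.asarray(image, dtype=float)


def mask_embryo(image, closing_radius: int = 10,
                min_object_area: int = 64,
                smoothing_sigma: float = 2.0) -> EmbryoMask:
    """Mask the embryo from the nuclear channel.

    Foreground is found by Otsu thresholding the lightly smoothed,
    log-transformed nuclear channel: in log space the gap between the dark extra-embryonic
    background and embryo signal (cytoplasmic level and nuclei) dominates
    the gap between cytoplasm and nuclei, so the split lands at the embryo
    boundary. The mask is then closed, hole-filled and reduced to the single
    largest connected component, so stray debris away from the embryo is
    discarded.
    """
    img = _as_nuclear(image)
    if smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, smoothing_sigma)
    logimg = np.log1p(np.clip(img, 0, None))
    if logimg.max() == logimg.min():
        raise NoEmbryoError("image is constant; no embryo foreground")
    raw = logimg > otsu_threshold(logimg)
    if not raw.any():
        raise NoEmbryoError("no foreground above background level")
    if raw.all():
        raise NoEmbryoError("whole frame classified as foreground")
    # refine at half-height in linear space: the 50% crossing of the smoothed
    # edge sits on the true boundary, undoing the blur-induced dilation. The
    # embryo level is taken as the foreground lower quartile, i.e. the
    # cytoplasmic plateau rather than the bright nuclei.
    bg_level = float(np.median(img[~raw]))
    fg_level = float(np.percentile(img[raw], 25))
    raw = img > (bg_level + fg_level) / 2.0
    closed = ndi.binary_closing(raw, structure=disk(closing_radius))
    closed = ndi.binary_fill_holes(closed)
    closed = _drop_small(closed, min_object_area)
    labels, n = ndi.label(closed)
    if n == 0:
        raise NoEmbryoError("no embryo-sized foreground component")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = ndi.binary_fill_holes(labels == keep)
    return EmbryoMask(mask=mask, area=int(mask.sum()))


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's automated threshold, returned as the upper edge of the last
    below-threshold histogram bin (so spiky discrete histograms split
    exactly between classes)."""
    counts, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts.astype(float) / counts.sum()
    omega0 = np.cumsum(w)
    mu = np.cumsum(w * centers)
    mu_t = mu[-1]
    denom = omega0 * (1.0 - omega0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sb = np.where(denom > 0, (mu_t * omega0 - mu) ** 2 / denom, 0.0)
    return float(edges[int(np.argmax(sb[:-1])) + 1])


def _drop_small(binary: np.ndarray, min_size: int) -> np.ndarray:
    labels, n = ndi.label(binary)
    if n == 0:
        return binary
    sizes = ndi.sum_labels(np.ones_like(labels), labels,
                           np.arange(1, n + 1))
    keep = np.concatenate([[False], sizes >= min_size])
    return keep[labels]


def _principal_angle(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Displayed-CCW angle of the principal axis and the axis ratio."""
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    t = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)   # array coords (y down)
    common = np.sqrt(4.0 * mu11 ** 2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    ratio = np.sqrt(lam1 / max(lam2, 1e-12))
    return -np.rad2deg(t), float(ratio)


def _wrap_axis_angle(deg: float) -> float:
    """Fold an axis direction into (-90, 90]."""
    deg = (deg + 90.0) % 180.0 - 90.0
    return 90.0 if deg == -90.0 else deg


def max_feret(mask: np.ndarray) -> tuple[float, float]:
    """Maximum Feret (caliper) diameter of a mask and its displayed angle.

    Computed exactly from the convex hull of the foreground pixel corners.
    """
    rows, cols = np.nonzero(mask)
    # pixel corners so the caliper includes the full pixel footprint
    pts = np.concatenate([
        np.stack([cols + dc, rows + dr], axis=1)
        for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)])
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    diff = hp[:, None, :] - hp[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    dc, dr = hp[i] - hp[j]
    angle = _wrap_axis_angle(-np.rad2deg(np.arctan2(dr, dc)))
    return float(np.sqrt(d2[i, j])), float(angle)


def fit_embryo_frame(mask: EmbryoMask | np.ndarray,
                     anterior_end: str = "unresolved",
                     min_axis_ratio: float = 1.1) -> EmbryoFrame:
    """Fit the normalized embryo frame from a foreground mask.

    The AP axis is the long axis of the mask: the fitted (moment) ellipse
    orientation, cross-checked against the maximum-Feret-diameter direction
    (the two must agree within 5 degrees). Egg length is the maximum Feret
    diameter; egg height is the mask extent perpendicular to the axis. The 180-degree anterior/posterior ambiguity of an axis cannot be
    resolved from a mask alone, so ``anterior_end`` must be supplied by the
    caller (from acquisition metadata or generator ground truth); it defaults
    to ``"unresolved"`` and downstream AP-directional operations refuse to run
    until it is set.
    """
    m = mask.mask if isinstance(mask, EmbryoMask) else np.asarray(mask, bool)
    if not m.any():
        raise NoEmbryoError("empty mask")
    rows, cols = np.nonzero(m)
    moment_angle, ratio = _principal_angle(rows.astype(float),
                                           cols.astype(float))
    if ratio < min_axis_ratio:
        raise OrientationError(
            f"mask is near-circular (axis ratio {ratio:.3f} < "
            f"{min_axis_ratio}); AP orientation is ambiguous")
    feret_len, feret_angle = max_feret(m)
    # the moment-ellipse orientation is sub-degree accurate on pixelized
    # masks; the Feret direction (quantized by hull vertices) cross-checks it
    if abs(_wrap_axis_angle(moment_angle - feret_angle)) >= 5.0:
        raise OrientationError(
            f"ellipse orientation ({moment_angle:.1f} deg) and max-Feret "
            f"direction ({feret_angle:.1f} deg) disagree")
    rotation = _wrap_axis_angle(moment_angle)

    t = np.deg2rad(rotation)
    u = np.array([np.cos(t), -np.sin(t)])   # AP direction, (col, row) steps
    v = np.array([-u[1], u[0]])
    s = cols * u[0] + rows * u[1]
    q = cols * v[0] + rows * v[1]
    s_mid = (s.max() + s.min()) / 2.0
    q_mid = (q.max() + q.min()) / 2.0
    center_col = s_mid * u[0] + q_mid * v[0]
    center_row = s_mid * u[1] + q_mid * v[1]
    egg_height = float(q.max() - q.min()) + 1.0

    a = 2.0 * np.sqrt(max(_second_moment(s), 1e-12))
    b = 2.0 * np.sqrt(max(_second_moment(q), 1e-12))
    return EmbryoFrame(
        center=(float(center_row), float(center_col)),
        rotation_angle=rotation,
        egg_length=feret_len,
        egg_height=egg_height,
        anterior_end=anterior_end,
        feret_angle=feret_angle,
        ellipse_axes=(float(a), float(b)),
    )


def _second_moment(x: np.ndarray) -> float:
    return float(np.mean((x - x.mean()) ** 2))


@dataclass
class Segmentation:
    """Watershed nucleus segmentation: label raster + per-nucleus records."""

    labels: np.ndarray
    records: list[NucleusRecord]

    def __len__(self) -> int:
        return len(self.records)


def segment_nuclei(nuclear_channel: np.ndarray,
                   mask: EmbryoMask | np.ndarray,
                   min_area: float = 4.0,
                   seed_min_distance: int | None = None,
                   frame: EmbryoFrame | None = None) -> Segmentation:
    """Segment nuclei inside the embryo mask.

    Automated (Otsu) thresholding on the masked nuclear channel, removal of
    objects below ``min_area`` px^2, then a watershed on the negated distance
    transform to split fused nuclei. Watershed seeds are local maxima of the
    distance transform separated by at least ``seed_min_distance`` px
    (default: the median equivalent nucleus radius).
    """
    if min_area <= 0:
        raise InputError("min_area must be > 0")
    chan = np.asarray(nuclear_channel, dtype=float)
    m = mask.mask if isinstance(mask, EmbryoMask) else np.asarray(mask, bool)
    if chan.shape != m.shape:
        raise InputError("mask and channel shapes differ")
    vals = chan[m]
    if vals.size == 0 or vals.max() == vals.min():
        return Segmentation(labels=np.zeros_like(m, dtype=np.int32),
                            records=[])
    thr = otsu_threshold(vals)
    fg = (chan > thr) & m
    fg = _drop_small(fg, max(int(np.ceil(min_area)), 1))
    if not fg.any():
        return Segmentation(labels=np.zeros_like(m, dtype=np.int32),
                            records=[])

    distance = ndi.distance_transform_edt(fg)
    if seed_min_distance is None:
        comp = sk_label(fg)
        areas = np.array([p.area for p in regionprops(comp)], dtype=float)
        radius = np.sqrt(np.median(areas) / np.pi)
        seed_min_distance = max(3, int(round(radius)))
    peaks = peak_local_max(distance, min_distance=seed_min_distance,
                           labels=sk_label(fg), exclude_border=False)
    markers = np.zeros_like(fg, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=fg)

    records: list[NucleusRecord] = []
    out = np.zeros_like(labels)
    next_id = 1
    for p in regionprops(labels, intensity_image=chan):
        if p.area < min_area:
            continue
        out[labels == p.label] = next_id
        r, c = p.centroid
        ap = dv = None
        if frame is not None:
            ap_a, dv_a = frame.to_normalized(r, c)
            ap, dv = float(ap_a), float(dv_a)
        records.append(NucleusRecord(
            id=next_id, row=float(r), col=float(c), area=float(p.area),
            ap=ap, dv=dv, mean_ch1=float(p.intensity_mean)))
        next_id += 1
    return Segmentation(labels=out, records=records)


def measure_nuclei(segmentation: Segmentation,
                   reporter_channel: np.ndarray) -> list[NucleusRecord]:
    """Fill each nucleus's mean reporter intensity from its label footprint."""
    rep = np.asarray(reporter_channel, dtype=float)
    if rep.shape != segmentation.labels.shape:
        raise InputError("reporter raster shape does not match labels")
    if not segmentation.records:
        return []
    ids = [r.id for r in segmentation.records]
    means = ndi.mean(rep, labels=segmentation.labels, index=ids)
    out = []
    for rec, mu in zip(segmentation.records, means):
        out.append(NucleusRecord(
            id=rec.id, row=rec.row, col=rec.col, area=rec.area,
            ap=rec.ap, dv=rec.dv, mean_ch1=rec.mean_ch1,
            mean_ch2=float(mu)))
    return out
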