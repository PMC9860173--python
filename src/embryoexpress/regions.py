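"""Fixed-ROI germ-layer quantification and per-line significance calls.

Reporter intensity is read out with a circular ROI of constant size placed at
fixed normalized coordinates proxying the three germ layers at stage 5:
ectoderm (lateral), mesoderm (ventral) and endoderm (posterior). Per-line
changes versus a control are assessed with a two-tailed two-sample Student
t-test (pooled variance; Welch optional) and classified "up"/"down" when
significant at alpha, "unchanged" otherwise. No multiple-testing correction
is applied by default, matching the per-line p < 0.05 readout; a
Benjamini-Hochberg column can be added on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EmbryoImage
from .errors import InputError, PlacementError
from .frames import EmbryoFrame
from .simulate import DEFAULT_REGIONS


@dataclass
class RegionTriplet:
    """Mean reporter intensity in the three germ-layer proxy ROIs."""

    embryo_id: str
    ectoderm: float
    mesoderm: float
    endoderm: float
    roi_radius: float
    region_defs: dict[str, tuple[float, float]]


@dataclass
class LineComparison:
    """Per-line two-sample comparison against control."""

    line_id: str
    n_line: int
    n_control: int
    mean_line: float
    mean_control: float
    t: float
    p: float
    call: str                       # up | down | unchanged
    alpha: float = 0.05


def measure_regions(image: EmbryoImage,
                    frame: EmbryoFrame,
                    roi_radius: float = 15.0,
                    region_defs: dict[str, tuple[float, float]] | None = None,
                    mask: np.ndarray | None = None,
                    embryo_id: str = "embryo") -> RegionTriplet:
    """Mean reporter intensity in circular ROIs at fixed (AP, DV) positions.

    Every ROI must lie fully inside the embryo mask (the analytic ellipse of
    the frame when no mask is given); otherwise a placement error is raised.
    """
    frame.require_resolved()
    if roi_radius <= 0:
        raise InputError("roi_radius must be > 0")
    defs = region_defs or DEFAULT_REGIONS
    reporter = np.asarray(image.reporter, dtype=float)
    shape = reporter.shape
    if mask is None:
        ap_r, dv_r = frame.normalized_grid(shape)
        mask = (2 * (ap_r - 0.5)) ** 2 + (2 * (dv_r - 0.5)) ** 2 <= 1.0
    values: dict[str, float] = {}
    rr_all, cc_all = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                                 indexing="ij")
    for name, (ap, dv) in defs.items():
        r0, c0 = frame.to_pixel(ap, dv)
        r0, c0 = float(r0), float(c0)
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise PlacementError(f"ROI {name!r} centre outside the image")
        roi = (rr_all - r0) ** 2 + (cc_all - c0) ** 2 <= roi_radius ** 2
        if not roi.any():
            raise PlacementError(f"ROI {name!r} covers no pixels")
        if not mask[roi].all():
            raise PlacementError(
                f"ROI {name!r} (radius {roi_radius} px) leaves the embryo "
                f"mask at (AP={ap}, DV={dv})")
        values[name] = float(reporter[roi].mean())
    missing = {"ectoderm", "mesoderm", "endoderm"} - set(values)
    if missing:
        raise InputError(f"region_defs misses required regions: {missing}")
    return RegionTriplet(embryo_id=embryo_id, ectoderm=values["ectoderm"],
                         mesoderm=values["mesoderm"],
                         endoderm=values["endoderm"],
                         roi_radius=roi_radius, region_defs=dict(defs))


def two_tailed_t(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test.

    Student's pooled-variance statistic by default; Welch's unequal-variance
    form with ``welch=True``. Two identical constant samples give (0, 1) by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def classify_line(line_values, control_values,
                  alpha: float = 0.05,
                  line_id: str = "line",
                  welch: bool = False) -> LineComparison:
    """Call a line "up"/"down"/"unchanged" versus control at level alpha."""
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must lie in (0, 1)")
    a = np.asarray(line_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    t, p = two_tailed_t(a, b, welch=welch)
    if p < alpha:
        call = "up" if a.mean() > b.mean() else "down"
    else:
        call = "unchanged"
    return LineComparison(line_id=line_id, n_line=a.size, n_control=b.size,
                          mean_line=float(a.mean()),
                          mean_control=float(b.mean()),
                          t=t, p=p, call=call, alpha=alpha)


def comparison_table(comparisons: list[LineComparison],
                     bh_correct: bool = False) -> pd.DataFrame:
    """Tabulate per-line comparisons; optional Benjamini-Hochberg column."""
    df = pd.DataFrame([{
        "line_id": c.line_id, "n_line": c.n_line, "n_control": c.n_control,
        "mean_line": c.mean_line, "mean_control": c.mean_control,
        "t": c.t, "p": c.p, "call": c.call,
    } for c in comparisons])
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["p_bh"] = q
    return df


def triplets_to_frame(triplets: list[RegionTriplet]) -> pd.DataFrame:
    return pd.DataFrame([{
        "embryo_id": t.embryo_id, "ectoderm": t.ectoderm,
        "mesoderm": t.mesoderm, "endoderm": t.endoderm,
        "roi_radius": t.roi_radius,
    } for t in triplets])
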