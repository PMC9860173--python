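"""Nucleus-based stripe detection and width measurement.

The rhoNEE-style procedure, operating on a segmented nucleus table in
normalized (AP, DV) coordinates:

1. bin nuclei by AP coordinate;
2. within each bin, compute a kernel-smoothed mean-fluorescence profile
   along DV;
3. find peaks in each bin's profile;
4. link peaks across adjacent bins (nearest DV under a maximum-jump
   constraint) into stripe traces.

Nuclei whose DV position falls inside a peak's half-maximum interval (taken
relative to the bin profile's local baseline) belong to the stripe; an
explicit include/exclude override stands in for manual curation. Each stripe
is then fitted along AP with a piecewise-linear midline (orthogonal
least-squares per segment) and, for every segment, the width is the largest
perpendicular spread between centres of the nuclei assigned to it; the
overall stripe width is the mean of the segment widths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .core import NucleusRecord
from .errors import DegenerateGeometryError, InputError


@dataclass
class StripeParams:
    """Tunable stripe-calling parameters (all in normalized fractions)."""

    bin_width: float = 0.05          # AP bin width
    grid_step: float = 0.01          # DV profile grid step
    sigma: float = 0.02              # DV smoothing kernel sd
    prominence_fraction: float = 0.25  # of the bin profile's range
    max_jump: float = 0.05           # max DV shift between adjacent bins
    min_span_fraction: float = 0.60  # of non-empty bins a trace must cover
    segment_length: float = 0.40     # AP length of midline segments
    # automated curation: require members to also reach the half-maximum
    # fluorescence level, which drops dim off-stripe nuclei that fall inside
    # the DV interval when a stripe crosses AP bins obliquely
    intensity_filter: bool = True


@dataclass
class APBin:
    index: int
    lo: float
    hi: float
    member_ids: list[int]


@dataclass
class DVProfile:
    bin_index: int
    grid: np.ndarray
    values: np.ndarray               # NaN where no nuclei contribute
    empty: bool = False


@dataclass
class StripePeak:
    bin_index: int
    dv: float
    height: float
    half_lo: float
    half_hi: float
    half_level: float = float("-inf")   # fluorescence at half maximum


@dataclass
class StripeTrace:
    peaks: list[StripePeak] = field(default_factory=list)

    @property
    def bin_indices(self) -> list[int]:
        return [p.bin_index for p in self.peaks]

    def peak_in(self, bin_index: int) -> StripePeak | None:
        for p in self.peaks:
            if p.bin_index == bin_index:
                return p
        return None


@dataclass
class StripeSegment:
    start: tuple[float, float]       # (ap, dv)
    end: tuple[float, float]
    width: float
    member_ids: list[int]


@dataclass
class StripeMeasurement:
    member_ids: list[int]
    segments: list[StripeSegment]
    overall_width: float


def _require_normalized(nuclei: list[NucleusRecord]) -> None:
    for r in nuclei:
        if r.ap is None or r.dv is None:
            raise InputError(
                f"nucleus {r.id} lacks normalized (AP, DV) coordinates")


def bin_nuclei(nuclei: list[NucleusRecord], bin_width: float = 0.05) -> list[APBin]:
    """Partition nuclei into half-open AP bins tiling [0, 1].

    A nucleus with AP exactly on a boundary goes to the bin whose interval
    starts there (right-open convention); AP = 1 goes to the last bin.
    """
    if not 0.0 < bin_width <= 1.0:
        raise InputError("bin_width must lie in (0, 1]")
    _require_normalized(nuclei)
    n_bins = int(np.ceil(1.0 / bin_width - 1e-12))
    bins = [APBin(index=i, lo=i * bin_width,
                  hi=min((i + 1) * bin_width, 1.0), member_ids=[])
            for i in range(n_bins)]
    for r in nuclei:
        i = int(np.clip(int(r.ap / bin_width), 0, n_bins - 1))
        bins[i].member_ids.append(r.id)
    return bins


def bin_dv_profile(ap_bin: APBin,
                   nuclei: list[NucleusRecord],
                   grid_step: float = 0.01,
                   sigma: float = 0.02) -> DVProfile:
    """Kernel-smoothed mean nuclear fluorescence along DV for one AP bin.

    Nadaraya-Watson estimate with a Gaussian kernel of sd ``sigma`` over the
    member nuclei's (DV, reporter-mean) pairs; grid points farther than ~3
    sigma from every nucleus get NaN. An empty bin yields a flagged empty
    profile, not an error.
    """
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    by_id = {r.id: r for r in nuclei}
    members = [by_id[i] for i in ap_bin.member_ids if i in by_id]
    if not members:
        return DVProfile(bin_index=ap_bin.index, grid=grid,
                         values=np.full_like(grid, np.nan), empty=True)
    dv = np.array([r.dv for r in members])
    val = np.array([r.mean_ch2 for r in members])
    w = np.exp(-0.5 * ((grid[:, None] - dv[None, :]) / sigma) ** 2)
    wsum = w.sum(axis=1)
    prof = np.full_like(grid, np.nan)
    ok = wsum > 1e-4
    prof[ok] = (w @ val)[ok] / wsum[ok]
    return DVProfile(bin_index=ap_bin.index, grid=grid, values=prof)


def _half_max_interval(profile: DVProfile, peak_idx: int,
                       baseline: float) -> tuple[float, float]:
    """DV interval where the profile exceeds half the peak height above the
    local baseline, found by walking outwards with linear interpolation."""
    g, v = profile.grid, profile.values
    half = baseline + 0.5 * (v[peak_idx] - baseline)

    def walk(step):
        i = peak_idx
        while 0 <= i + step < len(g):
            j = i + step
            if np.isnan(v[j]) or v[j] < half:
                if np.isnan(v[j]):
                    return g[i]
                frac = (v[i] - half) / max(v[i] - v[j], 1e-12)
                return g[i] + frac * (g[j] - g[i])
            i = j
        return g[i]

    return float(walk(-1)), float(walk(+1))


def detect_stripes(bins: list[APBin],
                   nuclei: list[NucleusRecord],
                   params: StripeParams | None = None) -> list[StripeTrace]:
    """Find peaks per AP bin and link them across bins into stripe traces."""
    params = params or StripeParams()
    if len(bins) < 3:
        raise InputError("need at least 3 AP bins")
    profiles = [bin_dv_profile(b, nuclei, params.grid_step, params.sigma)
                for b in bins]
    n_nonempty = sum(not p.empty for p in profiles)

    open_traces: list[StripeTrace] = []
    closed: list[StripeTrace] = []
    prev_nonempty: int | None = None
    for b, prof in zip(bins, profiles):
        if prof.empty:
            continue
        finite = np.nan_to_num(prof.values, nan=np.nanmin(prof.values))
        rng_ = finite.max() - finite.min()
        peaks_here: list[StripePeak] = []
        # profiles flat to numerical precision carry no peaks
        if rng_ > 1e-6 * max(1.0, np.abs(finite).max()):
            idx, _ = find_peaks(finite,
                                prominence=params.prominence_fraction * rng_)
            baseline = float(np.nanmin(prof.values))
            for i in idx:
                lo, hi = _half_max_interval(prof, i, baseline)
                level = baseline + 0.5 * (float(prof.values[i]) - baseline)
                peaks_here.append(StripePeak(
                    bin_index=b.index, dv=float(prof.grid[i]),
                    height=float(prof.values[i]), half_lo=lo, half_hi=hi,
                    half_level=level))
        adjacent = (prev_nonempty is not None
                    and b.index - prev_nonempty == 1)
        if not adjacent:
            closed.extend(open_traces)
            open_traces = []
        # greedy nearest-DV matching between open traces and new peaks; a
        # peak also matches when it falls inside the previous half-maximum
        # interval (broad stripes have plateau peaks that wander within it)
        def _linkable(last: StripePeak, p: StripePeak) -> bool:
            return (abs(last.dv - p.dv) <= params.max_jump
                    or last.half_lo <= p.dv <= last.half_hi
                    or p.half_lo <= last.dv <= p.half_hi)

        pairs = sorted(
            ((abs(t.peaks[-1].dv - p.dv), ti, pi)
             for ti, t in enumerate(open_traces)
             for pi, p in enumerate(peaks_here)
             if _linkable(t.peaks[-1], p)),
            key=lambda x: x[0])
        used_t: set[int] = set()
        used_p: set[int] = set()
        for _, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            open_traces[ti].peaks.append(peaks_here[pi])
            used_t.add(ti)
            used_p.add(pi)
        still_open = [t for ti, t in enumerate(open_traces) if ti in used_t]
        closed.extend(t for ti, t in enumerate(open_traces)
                      if ti not in used_t)
        for pi, p in enumerate(peaks_here):
            if pi not in used_p:
                still_open.append(StripeTrace(peaks=[p]))
        open_traces = still_open
        prev_nonempty = b.index
    closed.extend(open_traces)

    min_span = params.min_span_fraction * max(n_nonempty, 1)
    return [t for t in closed if len(t.peaks) >= min_span]


def assign_membership(trace: StripeTrace,
                      bins: list[APBin],
                      nuclei: list[NucleusRecord],
                      include: list[int] | None = None,
                      exclude: list[int] | None = None,
                      intensity_filter: bool = False) -> list[int]:
    """Collect nuclei belonging to a stripe trace.

    Within each bin carrying a peak, member nuclei are those whose DV lies
    inside the peak's half-maximum interval. With ``intensity_filter`` a
    member must in addition itself reach the half-maximum fluorescence level
    (automated curation: oblique stripes otherwise pick up dim off-stripe
    nuclei at the corners of axis-aligned bins). ``include``/``exclude`` id
    lists are the manual-curation override and are honoured verbatim.
    """
    by_index = {b.index: b for b in bins}
    by_id = {r.id: r for r in nuclei}
    members: set[int] = set()
    for peak in trace.peaks:
        if peak.bin_index not in by_index:
            raise InputError(f"trace references unknown bin {peak.bin_index}")
        for nid in by_index[peak.bin_index].member_ids:
            r = by_id.get(nid)
            if r is None or not peak.half_lo <= r.dv <= peak.half_hi:
                continue
            if intensity_filter and r.mean_ch2 < peak.half_level:
                continue
            members.add(nid)
    members |= set(include or [])
    members -= set(exclude or [])
    return sorted(members)


def measure_stripe(member_ids: list[int],
                   nuclei: list[NucleusRecord],
                   segment_length: float = 0.20) -> StripeMeasurement:
    """Piecewise-linear midline fit and perpendicular-width measurement.

    Members are split into consecutive AP segments of length
    ``segment_length``; each segment's midline is the orthogonal
    least-squares line through its members (so the width is measured truly
    perpendicular to the stripe, independent of its tilt); the segment width
    is the largest perpendicular spread between member centres. Segments with
    fewer than 2 members contribute no width. Overall width is the arithmetic
    mean of segment widths.
    """
    if segment_length <= 0:
        raise InputError("segment_length must be > 0")
    by_id = {r.id: r for r in nuclei}
    members = [by_id[i] for i in member_ids if i in by_id]
    _require_normalized(members)
    if len(members) < 2:
        raise InputError("need at least 2 member nuclei")
    ap = np.array([r.ap for r in members])
    dv = np.array([r.dv for r in members])
    ids = np.array([r.id for r in members])
    span = ap.max() - ap.min()
    if span < 1e-9:
        raise DegenerateGeometryError(
            "all member nuclei share one AP position")

    n_seg = max(int(np.ceil(span / segment_length - 1e-12)), 1)
    edges = ap.min() + np.arange(n_seg + 1) * (span / n_seg)
    seg_idx = np.clip(np.searchsorted(edges, ap, side="right") - 1,
                      0, n_seg - 1)
    segments: list[StripeSegment] = []
    widths = []
    for s in range(n_seg):
        in_seg = seg_idx == s
        if in_seg.sum() < 2:
            continue
        x, y = ap[in_seg], dv[in_seg]
        cx, cy = x.mean(), y.mean()
        cov = np.cov(np.stack([x - cx, y - cy]))
        evals, evecs = np.linalg.eigh(cov)
        direction = evecs[:, np.argmax(evals)]
        if direction[0] < 0:
            direction = -direction
        normal = np.array([-direction[1], direction[0]])
        along = (x - cx) * direction[0] + (y - cy) * direction[1]
        perp = (x - cx) * normal[0] + (y - cy) * normal[1]
        width = float(perp.max() - perp.min())
        p0 = (float(cx + along.min() * direction[0]),
              float(cy + along.min() * direction[1]))
        p1 = (float(cx + along.max() * direction[0]),
              float(cy + along.max() * direction[1]))
        segments.append(StripeSegment(start=p0, end=p1, width=width,
                                      member_ids=ids[in_seg].tolist()))
        widths.append(width)
    if not widths:
        raise DegenerateGeometryError("no segment holds >= 2 member nuclei")
    return StripeMeasurement(member_ids=sorted(ids.tolist()),
                             segments=segments,
                             overall_width=float(np.mean(widths)))


def call_stripes(nuclei: list[NucleusRecord],
                 params: StripeParams | None = None,
                 include: dict[int, list[int]] | None = None,
                 exclude: dict[int, list[int]] | None = None,
                 ) -> list[tuple[StripeTrace, StripeMeasurement]]:
    """End-to-end stripe calling on a nucleus table.

    ``include``/``exclude`` map stripe index (in detection order) to nucleus
    id lists for manual curation.
    """
    params = params or StripeParams()
    bins = bin_nuclei(nuclei, params.bin_width)
    traces = detect_stripes(bins, nuclei, params)
    out = []
    for k, trace in enumerate(traces):
        members = assign_membership(
            trace, bins, nuclei,
            include=(include or {}).get(k), exclude=(exclude or {}).get(k),
            intensity_filter=params.intensity_filter)
        measurement = measure_stripe(members, nuclei, params.segment_length)
        out.append((trace, measurement))
    return out


def stripes_to_json(results: list[tuple[StripeTrace, StripeMeasurement]],
                    path: str | Path) -> Path:
    path = Path(path)
    payload = []
    for trace, m in results:
        payload.append({
            "peaks": [{"bin": p.bin_index, "dv": p.dv, "height": p.height,
                       "half_lo": p.half_lo, "half_hi": p.half_hi}
                      for p in trace.peaks],
            "segments": [{"start": s.start, "end": s.end, "width": s.width,
                          "n_members": len(s.member_ids)}
                         for s in m.segments],
            "overall_width": m.overall_width,
            "n_members": len(m.member_ids),
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def stripes_to_bed(results: list[tuple[StripeTrace, StripeMeasurement]],
                   path: str | Path, scale: int = 1000) -> Path:
    """BED-like interval table of stripe segments in mil-units of AP/DV."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, (_, m) in enumerate(results):
            for s in m.segments:
                fh.write(f"stripe_{k}\t{int(s.start[0] * scale)}\t"
                         f"{int(s.end[0] * scale)}\t"
                         f"dv={s.start[1]:.3f}-{s.end[1]:.3f}\t"
                         f"{s.width:.4f}\t+\n")
    return path
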