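"""Analytic expression-pattern primitives on the normalized embryo frame.

A :class:`PatternSpec` is a sum of primitives plus a baseline, evaluated at
normalized (AP, DV) coordinates. Primitives mimic the canonical early-embryo
reporter patterns: AP stripes (eve-stripe-like), DV bands, paired lateral
neurogenic-ectoderm domains, a ventral presumptive-mesoderm domain and a
posterior presumptive-endoderm cap. Stripe and band cross-sections are
Gaussian; the posterior cap is a logistic step along AP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

# fixed geometry of the composite domains (normalized units)
LATERAL_CENTERS = (0.25, 0.75)
LATERAL_SIGMA = 0.08
VENTRAL_CENTER = 0.85
VENTRAL_SIGMA = 0.07
POSTERIOR_EDGE = 0.85
POSTERIOR_SOFTNESS = 0.03

PRIMITIVE_KINDS = ("ap_stripe", "dv_band", "lateral_domain",
                   "ventral_domain", "posterior_domain", "uniform")


@dataclass(frozen=True)
class Primitive:
    """One additive pattern component.

    ``center``/``sigma`` (fractions of egg length or height) are required for
    ``ap_stripe`` and ``dv_band`` and ignored for the fixed-geometry domains.
    """

    kind: str
    amplitude: float
    center: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.kind not in PRIMITIVE_KINDS:
            raise InputError(f"unknown primitive kind {self.kind!r}")
        if self.amplitude < 0:
            raise InputError("amplitude must be >= 0")
        if self.kind in ("ap_stripe", "dv_band"):
            if self.center is None or self.sigma is None:
                raise InputError(f"{self.kind} requires center and sigma")
            if not (0 < self.center < 1) or not (0 < self.sigma < 1):
                raise InputError("center and sigma must lie in (0, 1)")


def ap_stripe(center: float, sigma: float, amplitude: float) -> Primitive:
    return Primitive("ap_stripe", amplitude, center, sigma)


def dv_band(center: float, sigma: float, amplitude: float) -> Primitive:
    return Primitive("dv_band", amplitude, center, sigma)


def lateral_domain(amplitude: float) -> Primitive:
    return Primitive("lateral_domain", amplitude)


def ventral_domain(amplitude: float) -> Primitive:
    return Primitive("ventral_domain", amplitude)


def posterior_domain(amplitude: float) -> Primitive:
    return Primitive("posterior_domain", amplitude)


def uniform(amplitude: float) -> Primitive:
    return Primitive("uniform", amplitude)


@dataclass
class PatternSpec:
    """Additive expression pattern: sum of primitives plus a baseline."""

    primitives: list[Primitive] = field(default_factory=list)
    baseline: float = 0.0

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "primitives": [{
                "kind": p.kind, "amplitude": p.amplitude,
                "center": p.center, "sigma": p.sigma,
            } for p in self.primitives],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternSpec":
        prims = [Primitive(p["kind"], p["amplitude"],
                           p.get("center"), p.get("sigma"))
                 for p in d.get("primitives", [])]
        return cls(primitives=prims, baseline=float(d.get("baseline", 0.0)))


def _gauss(x, center, sigma):
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def pattern_value(spec: PatternSpec, ap, dv):
    """Evaluate a pattern at normalized coordinates.

    ``ap`` and ``dv`` may be scalars or broadcastable arrays with values in
    [0, 1]; returns intensity in arbitrary units.
    """
    ap = np.asarray(ap, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if np.any(ap < 0) or np.any(ap > 1) or np.any(dv < 0) or np.any(dv > 1):
        raise InputError("ap and dv must lie in [0, 1]")
    out = np.full(np.broadcast(ap, dv).shape, float(spec.baseline))
    for p in spec.primitives:
        if p.kind == "ap_stripe":
            out = out + p.amplitude * _gauss(ap, p.center, p.sigma)
        elif p.kind == "dv_band":
            out = out + p.amplitude * _gauss(dv, p.center, p.sigma)
        elif p.kind == "lateral_domain":
            out = out + p.amplitude * (
                _gauss(dv, LATERAL_CENTERS[0], LATERAL_SIGMA)
                + _gauss(dv, LATERAL_CENTERS[1], LATERAL_SIGMA))
        elif p.kind == "ventral_domain":
            out = out + p.amplitude * _gauss(dv, VENTRAL_CENTER, VENTRAL_SIGMA)
        elif p.kind == "posterior_domain":
            out = out + p.amplitude / (
                1.0 + np.exp(-(ap - POSTERIOR_EDGE) / POSTERIOR_SOFTNESS))
        elif p.kind == "uniform":
            out = out + p.amplitude
    return out if out.shape else float(out)
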