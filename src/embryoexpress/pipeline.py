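"""End-to-end orchestration: simulate -> mask -> frame -> quantify -> test.

A :class:`RunConfig` describes one reporter line versus its control: embryo
geometry, expression pattern, a line-specific amplitude scaling (the
"effect"), noise, ROI geometry and the test parameters. ``run_quantification``
renders (or will later load) the embryos, pushes every one through the full
measurement pipeline (mask, axis fit, fixed-ROI germ-layer readout), then
compares line and control in the chosen region with a two-tailed t-test.

Reproducibility: the single run seed fans out to per-embryo child seeds
through ``numpy.random.SeedSequence.spawn``, so any embryo can be regenerated
in isolation, and the whole run is byte-identical under a fixed config+seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, EmbryoExpressError, EmptyRunError
from .imaging import fit_embryo_frame, mask_embryo
from .patterns import PatternSpec, Primitive
from .regions import (LineComparison, RegionTriplet, classify_line,
                      measure_regions, triplets_to_frame)
from .simulate import DEFAULT_REGIONS, EmbryoGeometry, render_embryo

log = logging.getLogger("embryoexpress")


@dataclass
class RunConfig:
    """Parameters of one line-versus-control quantification run."""

    line_id: str = "line"
    seed: int = 0
    n_line: int = 5
    n_control: int = 5
    # geometry
    semi_major: float = 300.0
    semi_minor: float = 120.0
    rotation_angle: float = 0.0
    anterior_end: str = "left"
    # pattern: list of primitive dicts + baseline; the line's primitive
    # amplitudes are multiplied by effect_scale
    pattern: list = field(default_factory=lambda: [
        {"kind": "ventral_domain", "amplitude": 400.0}])
    baseline: float = 50.0
    effect_scale: float = 1.0
    # rendering
    n_nuclei: int = 500
    nucleus_radius: float = 4.0
    nucleus_min_sep: float = 10.0
    noise_sd: float = 20.0
    # quantification
    roi_radius: float = 15.0
    test_region: str = "mesoderm"
    alpha: float = 0.05
    welch: bool = False

    _FIELDS = None  # filled in below

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in d:
            if key not in known:
                raise ConfigError(f"unknown configuration key {key!r}",
                                  key=key)
        cfg = cls(**d)
        if cfg.test_region not in DEFAULT_REGIONS:
            raise ConfigError(
                f"test_region must be one of {sorted(DEFAULT_REGIONS)}",
                key="test_region")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LineReport:
    """Machine-readable result of one quantification run."""

    line_id: str
    triplets_line: list[RegionTriplet]
    triplets_control: list[RegionTriplet]
    comparison: LineComparison
    config: dict
    config_hash: str
    version: str
    embryo_errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def trip(t: RegionTriplet) -> dict:
            return {"embryo_id": t.embryo_id, "ectoderm": t.ectoderm,
                    "mesoderm": t.mesoderm, "endoderm": t.endoderm}

        return {
            "schema_version": 1,
            "line_id": self.line_id,
            "line": [trip(t) for t in self.triplets_line],
            "control": [trip(t) for t in self.triplets_control],
            "comparison": {
                "n_line": self.comparison.n_line,
                "n_control": self.comparison.n_control,
                "mean_line": self.comparison.mean_line,
                "mean_control": self.comparison.mean_control,
                "t": self.comparison.t,
                "p": self.comparison.p,
                "call": self.comparison.call,
                "alpha": self.comparison.alpha,
            },
            "config": self.config,
            "config_hash": self.config_hash,
            "version": self.version,
            "embryo_errors": self.embryo_errors,
        }


def _pattern_from_config(cfg: RunConfig, scale: float) -> PatternSpec:
    prims = [Primitive(p["kind"], p["amplitude"] * scale,
                       p.get("center"), p.get("sigma"))
             for p in cfg.pattern]
    return PatternSpec(primitives=prims, baseline=cfg.baseline)


def _quantify_embryo(cfg: RunConfig, spec: PatternSpec, seed: int,
                     embryo_id: str) -> RegionTriplet:
    geometry = EmbryoGeometry(semi_major=cfg.semi_major,
                              semi_minor=cfg.semi_minor,
                              rotation_angle=cfg.rotation_angle,
                              anterior_end=cfg.anterior_end)
    image, _ = render_embryo(
        geometry, spec,
        nuclei=(cfg.n_nuclei, cfg.nucleus_radius, cfg.nucleus_min_sep),
        noise=cfg.noise_sd, seed=seed)
    mask = mask_embryo(image)
    frame = fit_embryo_frame(mask, anterior_end=cfg.anterior_end)
    return measure_regions(image, frame, roi_radius=cfg.roi_radius,
                           mask=mask.mask, embryo_id=embryo_id)


def run_quantification(config: RunConfig) -> LineReport:
    """Execute the staged pipeline for one line and its control.

    Per-embryo failures are recorded in the report and skipped; the run only
    fails outright if a group ends up without usable embryos.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_line + config.n_control)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]

    spec_line = _pattern_from_config(config, config.effect_scale)
    spec_ctrl = _pattern_from_config(config, 1.0)

    triplets_line: list[RegionTriplet] = []
    triplets_ctrl: list[RegionTriplet] = []
    errors: list[str] = []
    for i in range(config.n_line):
        eid = f"{config.line_id}_{i + 1:02d}"
        try:
            triplets_line.append(
                _quantify_embryo(config, spec_line, seeds[i], eid))
        except EmbryoExpressError as exc:
            errors.append(f"{eid}: {exc}")
    for i in range(config.n_control):
        eid = f"control_{i + 1:02d}"
        try:
            triplets_ctrl.append(_quantify_embryo(
                config, spec_ctrl, seeds[config.n_line + i], eid))
        except EmbryoExpressError as exc:
            errors.append(f"{eid}: {exc}")
    log.info("run %s: %d/%d line, %d/%d control embryos quantified",
             config.line_id, len(triplets_line), config.n_line,
             len(triplets_ctrl), config.n_control)
    if len(triplets_line) < 2 or len(triplets_ctrl) < 2:
        raise EmptyRunError(
            f"too few usable embryos (line {len(triplets_line)}, control "
            f"{len(triplets_ctrl)}); errors: {errors}")

    region = config.test_region
    line_vals = [getattr(t, region) for t in triplets_line]
    ctrl_vals = [getattr(t, region) for t in triplets_ctrl]
    comparison = classify_line(line_vals, ctrl_vals, alpha=config.alpha,
                               line_id=config.line_id, welch=config.welch)
    return LineReport(line_id=config.line_id,
                      triplets_line=triplets_line,
                      triplets_control=triplets_ctrl,
                      comparison=comparison,
                      config=config.to_dict(),
                      config_hash=config.config_hash(),
                      version=__version__,
                      embryo_errors=errors)


def write_report(report: LineReport, outdir: str | Path,
                 formats: tuple[str, ...] = ("csv", "json")) -> dict:
    """Write a report as CSV table(s) and/or JSON; values are identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "json" in formats:
        js = outdir / f"{report.line_id}_report.json"
        with open(js, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        paths["json"] = js
    if "csv" in formats:
        csv = outdir / f"{report.line_id}_regions.csv"
        df = triplets_to_frame(report.triplets_line
                               + report.triplets_control)
        df.insert(0, "group", ["line"] * len(report.triplets_line)
                  + ["control"] * len(report.triplets_control))
        df.to_csv(csv, index=False)
        paths["csv"] = csv
        comp = outdir / f"{report.line_id}_comparison.csv"
        c = report.comparison
        with open(comp, "w") as fh:
            fh.write("line_id,n_line,n_control,mean_line,mean_control,"
                     "t,p,call\n")
            fh.write(f"{c.line_id},{c.n_line},{c.n_control},"
                     f"{c.mean_line!r},{c.mean_control!r},{c.t!r},{c.p!r},"
                     f"{c.call}\n")
        paths["comparison"] = comp
    return paths
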