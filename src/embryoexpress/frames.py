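"""Normalized embryo coordinate frame.

Convention shared by every module:

* AP (anterior-posterior) fraction: 0 = anterior, 1 = posterior;
* DV (dorsoventral) fraction: 0 = dorsal, 1 = ventral;
* images are row-major with row 0 at the top, so with a horizontal embryo and
  anterior on the left, AP increases with column and DV with row;
* ``rotation_angle`` is the angle in degrees of the AP axis measured
  counter-clockwise (as displayed) from the image x-axis. The rotation that
  must be *applied* to make the AP axis horizontal is ``-rotation_angle``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import OrientationError


@dataclass
class EmbryoFrame:
    """Pixel <-> normalized (AP, DV) transform for one embryo.

    ``center`` is (row, col) in pixels; ``egg_length``/``egg_height`` are the
    AP and DV extents in pixels; ``anterior_end`` says which end of the long
    axis is anterior after derotation ("left", "right" or "unresolved").
    """

    center: tuple[float, float]
    rotation_angle: float          # degrees CCW (displayed) of AP axis from x
    egg_length: float              # px, along AP
    egg_height: float              # px, along DV
    anterior_end: str = "unresolved"
    feret_angle: float | None = None
    ellipse_axes: tuple[float, float] | None = None  # (semi-major, semi-minor)

    @property
    def resolved(self) -> bool:
        return self.anterior_end in ("left", "right")

    @property
    def rotation_applied(self) -> float:
        """Rotation in degrees that aligns the AP axis with the x-axis."""
        return -self.rotation_angle

    def require_resolved(self) -> None:
        if not self.resolved:
            raise OrientationError(
                "anterior/posterior orientation is unresolved; supply "
                "anterior_end metadata before extracting AP quantities")

    def _axes_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        # In array coordinates (x=col, y=row, y growing downwards) a
        # displayed-CCW angle theta corresponds to direction (cos t, -sin t).
        t = np.deg2rad(self.rotation_angle)
        u = np.array([np.cos(t), -np.sin(t)])   # AP axis, (col, row) steps
        v = np.array([-u[1], u[0]])             # DV axis (towards ventral)
        return u, v

    def to_normalized(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        """Map pixel positions to (AP, DV) fractions (may fall outside [0,1])."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        u, v = self._axes_vectors()
        dc = cols - self.center[1]
        dr = rows - self.center[0]
        s = dc * u[0] + dr * u[1]
        q = dc * v[0] + dr * v[1]
        ap = 0.5 + s / self.egg_length
        dv = 0.5 + q / self.egg_height
        if self.anterior_end == "right":
            ap = 1.0 - ap
        return ap, dv

    def to_pixel(self, ap, dv) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`to_normalized`; returns (rows, cols)."""
        ap = np.asarray(ap, dtype=float)
        dv = np.asarray(dv, dtype=float)
        if self.anterior_end == "right":
            ap = 1.0 - ap
        u, v = self._axes_vectors()
        s = (ap - 0.5) * self.egg_length
        q = (dv - 0.5) * self.egg_height
        cols = self.center[1] + s * u[0] + q * v[0]
        rows = self.center[0] + s * u[1] + q * v[1]
        return rows, cols

    def normalized_grid(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(AP, DV) fraction rasters for every pixel of an image of ``shape``."""
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        return self.to_normalized(rr, cc)
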