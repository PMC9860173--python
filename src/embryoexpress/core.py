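"""Core in-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError


@dataclass
class EmbryoImage:
    """Two-channel embryo max-projection.

    ``nuclear`` is the nuclear-stain channel (DAPI-like), ``reporter`` the
    reporter channel, both uint16 rasters of identical shape. ``pixel_size``
    is in micrometres per pixel (isotropic) and is carried as provenance; the
    analyses work in pixels and normalized fractions.
    """

    nuclear: np.ndarray
    reporter: np.ndarray
    pixel_size: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.nuclear.shape != self.reporter.shape:
            raise InputError("nuclear and reporter channels differ in shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape

    def to_tiff(self, path: str | Path) -> Path:
        """Write a 2-page TIFF (page 0 = nuclear, page 1 = reporter)."""
        path = Path(path)
        stack = np.stack([self.nuclear, self.reporter]).astype(np.uint16)
        tifffile.imwrite(path, stack, metadata={"axes": "CYX"})
        return path

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float = 1.0) -> "EmbryoImage":
        arr = tifffile.imread(str(path))
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise InputError(
                f"{path}: expected a 2-channel stack, got shape {arr.shape}")
        return cls(nuclear=arr[0], reporter=arr[1], pixel_size=pixel_size,
                   metadata={"source": str(path)})


@dataclass
class NucleusRecord:
    """One segmented nucleus.

    Centroid is stored both in pixels (row, col) and, when an embryo frame is
    available, as normalized (AP, DV) fractions. ``mean_ch1`` is the nuclear
    stain mean, ``mean_ch2`` the reporter mean (a.u.).
    """

    id: int
    row: float
    col: float
    area: float
    ap: float | None = None
    dv: float | None = None
    mean_ch1: float = 0.0
    mean_ch2: float = 0.0


NUCLEI_COLUMNS = ["id", "row", "col", "ap", "dv", "area",
                  "mean_ch1", "mean_ch2"]


def nuclei_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "row": r.row, "col": r.col, "ap": r.ap, "dv": r.dv,
        "area": r.area, "mean_ch1": r.mean_ch1, "mean_ch2": r.mean_ch2,
    } for r in records], columns=NUCLEI_COLUMNS)


def frame_to_nuclei(df: pd.DataFrame) -> list[NucleusRecord]:
    recs = []
    for _, row in df.iterrows():
        recs.append(NucleusRecord(
            id=int(row["id"]), row=float(row["row"]), col=float(row["col"]),
            area=float(row["area"]),
            ap=None if pd.isna(row["ap"]) else float(row["ap"]),
            dv=None if pd.isna(row["dv"]) else float(row["dv"]),
            mean_ch1=float(row["mean_ch1"]), mean_ch2=float(row["mean_ch2"])))
    return recs


def write_nuclei_csv(records: list[NucleusRecord], path: str | Path) -> Path:
    path = Path(path)
    nuclei_to_frame(records).to_csv(path, index=False)
    return path


def read_nuclei_csv(path: str | Path) -> list[NucleusRecord]:
    return frame_to_nuclei(pd.read_csv(path))
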