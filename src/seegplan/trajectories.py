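"""Trajectory records and their CSV interchange format.

A trajectory is the planning atom: a straight electrode path from a cortical
entry point to a deep target point, labelled with the anatomical region of
interest (ROI) it samples, the hemisphere, and the patient it belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryError, Point3, Segment3, Space

Side = Literal["left", "right"]

CSV_COLUMNS = ["patient_id", "roi", "side", "ex", "ey", "ez", "tx", "ty", "tz", "space"]


@dataclass(frozen=True)
class Trajectory:
    entry: Point3
    target: Point3
    roi: str
    side: Side
    patient_id: str

    def __post_init__(self) -> None:
        if self.entry.space != self.target.space:
            raise GeometryError("entry and target must share a space")
        if np.allclose(self.entry.as_array(), self.target.as_array()):
            raise GeometryError("zero-length trajectory: entry equals target")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def space(self) -> Space:
        return self.entry.space

    @property
    def length(self) -> float:
        return self.entry.distance_to(self.target)

    def direction(self) -> np.ndarray:
        """Unit vector entry -> target."""
        d = self.target - self.entry
        return d / np.linalg.norm(d)

    def segment(self) -> Segment3:
        return Segment3(self.entry, self.target)


@dataclass
class TrajectorySet:
    """A cohort of trajectories, tagged as training or test material."""

    trajectories: list[Trajectory]
    cohort: Literal["training", "test"] = "training"

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def rois(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trajectories:
            seen.setdefault(t.roi, None)
        return list(seen)

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trajectories:
            seen.setdefault(t.patient_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trajectories:
            e, g = t.entry.as_array(), t.target.as_array()
            rows.append(
                dict(
                    patient_id=t.patient_id, roi=t.roi, side=t.side,
                    ex=e[0], ey=e[1], ez=e[2], tx=g[0], ty=g[1], tz=g[2],
                    space=t.space,
                )
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def save_csv(self, path: str | Path) -> None:
        # 17 significant digits so coordinates round-trip bit-exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort: str = "training") -> "TrajectorySet":
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        out = []
        for row in df.itertuples(index=False):
            space = row.space
            out.append(
                Trajectory(
                    entry=Point3(float(row.ex), float(row.ey), float(row.ez), space),
                    target=Point3(float(row.tx), float(row.ty), float(row.tz), space),
                    roi=str(row.roi),
                    side=str(row.side),
                    patient_id=str(row.patient_id),
                )
            )
        return cls(out, cohort=cohort)  # type: ignore[arg-type]

    @classmethod
    def load_csv(cls, path: str | Path, cohort: str = "training") -> "TrajectorySet":
        return cls.from_frame(
            pd.read_csv(path, float_precision="round_trip"), cohort=cohort
        )
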