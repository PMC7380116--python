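"""Template-space spatial priors for entry and target points.

Historical implantations are pooled across patients by mapping each
trajectory into a common group-template space (an affine surrogate for
MNI-152 normalization), combining hemispheres by reflecting left-sided
points across the midsagittal plane, and clustering per (ROI, role). A
prior is only created for an ROI/role targeted at least ``min_count``
times (default 5). Its dispersion is summarised by the within-cluster sum
of squares (WCSS), and membership of a prospective point is a binary test:
inside the centroid ball (max training-point spread plus a tolerance) AND
within a fixed radius of at least one training point. The intersection
keeps the region compact while letting it follow the cloud's shape; both
radii are configurable because the historical software never published its
boundary rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import (
    TEMPLATE,
    AffineTransform,
    GeometryError,
    Point3,
    SurfaceMesh,
    apply_affine,
    ray_mesh_first_intersection,
)
from .trajectories import Trajectory, TrajectorySet

PriorRole = Literal["entry", "target"]


class PriorError(ValueError):
    """Inconsistent prior construction or lookup."""


# --------------------------------------------------------------------------
# coordinate plumbing


def to_template(
    trajectory: Trajectory,
    affine: AffineTransform,
    cortex: SurfaceMesh | None = None,
) -> Trajectory:
    """Map a patient-space trajectory into the group template.

    The entry point is first re-derived, in patient space, as the
    intersection of the planned trajectory with the cortical surface (when a
    cortex mesh is supplied); entry and target are then pushed through the
    patient->template affine.
    """
    entry = trajectory.entry
    if cortex is not None:
        hit = ray_mesh_first_intersection(entry, trajectory.direction(), cortex)
        if hit is None:
            # entry already at/inside the surface: cast from outside instead
            back = Point3.from_array(
                entry.as_array() - 1000.0 * trajectory.direction(), entry.space
            )
            hit = ray_mesh_first_intersection(back, trajectory.direction(), cortex)
        if hit is not None:
            entry = hit
    return Trajectory(
        entry=apply_affine(affine, entry),
        target=apply_affine(affine, trajectory.target),
        roi=trajectory.roi,
        side=trajectory.side,
        patient_id=trajectory.patient_id,
    )


def flip_to_canonical(p: Point3, side: str) -> Point3:
    """Reflect left-hemisphere template points to the canonical right side.

    Left-side points map x -> -x; right-side points are unchanged. Applied
    strictly after the template transform (reflection does not commute with
    x-translation).
    """
    if p.space != TEMPLATE:
        raise GeometryError("hemisphere flipping is defined in template space")
    if side == "left":
        return Point3(-p.x, p.y, p.z, p.space)
    return p


def wcss(points: np.ndarray | Sequence) -> float:
    """Within-cluster sum of squares, sum of ||x - mean||^2, in mm^2."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise PriorError("WCSS of an empty point set")
    return float(np.sum((pts - pts.mean(axis=0)) ** 2))


# --------------------------------------------------------------------------
# priors


@dataclass
class SpatialPrior:
    """Template-space point cloud for one ROI/role with a membership rule."""

    roi: str
    role: PriorRole
    points: np.ndarray            # (n, 3) canonical template coordinates
    membership_radius: float      # centroid-ball radius, mm
    point_radius: float = 5.0     # per-training-point ball radius, mm

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self._tree = cKDTree(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> Point3:
        return Point3.from_array(self.points.mean(axis=0), TEMPLATE)

    @property
    def wcss(self) -> float:
        return wcss(self.points)

    def contains(self, p: Point3) -> bool:
        """Membership: inside the centroid ball AND near some training point."""
        if p.space != TEMPLATE:
            raise GeometryError("prior membership is tested in template space")
        q = p.as_array()
        if np.linalg.norm(q - self.points.mean(axis=0)) > self.membership_radius:
            return False
        return float(self._tree.query(q)[0]) <= self.point_radius

    def to_json(self) -> dict:
        c = self.centroid.as_array()
        return {
            "roi": self.roi,
            "role": self.role,
            "points": self.points.tolist(),
            "centroid": c.tolist(),
            "wcss": self.wcss,
            "membership_radius": self.membership_radius,
            "point_radius": self.point_radius,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SpatialPrior":
        return cls(
            roi=obj["roi"],
            role=obj["role"],
            points=np.array(obj["points"], dtype=float),
            membership_radius=float(obj["membership_radius"]),
            point_radius=float(obj.get("point_radius", 5.0)),
        )


@dataclass
class PriorSet:
    """Priors keyed by (roi, role), with cohort provenance."""

    priors: dict[tuple[str, PriorRole], SpatialPrior] = field(default_factory=dict)
    template: str = "mni152-surrogate"
    provenance: list[str] = field(default_factory=list)

    def has(self, roi: str, role: PriorRole) -> bool:
        return (roi, role) in self.priors

    def get(self, roi: str, role: PriorRole) -> SpatialPrior:
        try:
            return self.priors[(roi, role)]
        except KeyError:
            raise PriorError(f"no {role} prior for ROI {roi!r}") from None

    def rois(self) -> list[str]:
        seen: dict[str, None] = {}
        for roi, _ in self.priors:
            seen.setdefault(roi, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.priors)

    def to_json(self) -> dict:
        return {
            "template": self.template,
            "provenance": self.provenance,
            "priors": [p.to_json() for p in self.priors.values()],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def from_json(cls, obj: dict) -> "PriorSet":
        ps = cls(template=obj.get("template", "mni152-surrogate"),
                 provenance=list(obj.get("provenance", [])))
        for rec in obj["priors"]:
            p = SpatialPrior.from_json(rec)
            ps.priors[(p.roi, p.role)] = p
        return ps

    @classmethod
    def load(cls, path: str | Path) -> "PriorSet":
        return cls.from_json(json.loads(Path(path).read_text()))


def prior_from_points(
    roi: str,
    role: PriorRole,
    points: np.ndarray,
    membership_tolerance: float = 2.0,
    point_radius: float = 5.0,
) -> SpatialPrior:
    """Build one prior from a canonical template-space cloud.

    The centroid-ball radius is the maximum point-to-centroid distance plus
    ``membership_tolerance`` mm, so every training point is a member of its
    own prior.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    spread = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())
    return SpatialPrior(roi, role, pts, spread + membership_tolerance, point_radius)


def canonical_points(
    training: TrajectorySet,
    affines: Mapping[str, AffineTransform],
    cortex: SurfaceMesh | None = None,
) -> dict[tuple[str, PriorRole], list[np.ndarray]]:
    """Per-(roi, role) canonical template clouds from a patient-space cohort."""
    clouds: dict[tuple[str, PriorRole], list[np.ndarray]] = {}
    for traj in training:
        if traj.patient_id not in affines:
            raise PriorError(f"no patient->template affine for patient {traj.patient_id!r}")
        t = to_template(traj, affines[traj.patient_id], cortex=cortex)
        entry = flip_to_canonical(t.entry, t.side)
        target = flip_to_canonical(t.target, t.side)
        clouds.setdefault((traj.roi, "entry"), []).append(entry.as_array())
        clouds.setdefault((traj.roi, "target"), []).append(target.as_array())
    return clouds


def build_priors(
    training: TrajectorySet,
    affines: Mapping[str, AffineTransform],
    min_count: int = 5,
    exclusions: Sequence[str] = (),
    membership_tolerance: float = 2.0,
    point_radius: float = 5.0,
    entry_wcss_max: float | None = None,
    target_wcss_max: float | None = None,
    cortex: SurfaceMesh | None = None,
) -> PriorSet:
    """Build the full prior set from a historical cohort.

    A prior is emitted per (roi, role) only when the ROI was implanted at
    least ``min_count`` times and is not in ``exclusions`` (lesional /
    patient-specific targets). Optional per-role WCSS ceilings drop clouds
    too dispersed to constitute a usable prior (disabled by default); this
    is how an ROI can end up with a target prior but no entry prior.
    Output is independent of trajectory input order.
    """
    clouds = canonical_points(training, affines, cortex=cortex)
    ceilings = {"entry": entry_wcss_max, "target": target_wcss_max}
    ps = PriorSet(provenance=sorted(training.patient_ids()))
    excluded = set(exclusions)
    for (roi, role) in sorted(clouds):
        if roi in excluded:
            continue
        pts = np.array(clouds[(roi, role)])
        if len(pts) < min_count:
            continue
        ceiling = ceilings[role]
        if ceiling is not None and wcss(pts) > ceiling:
            continue
        ps.priors[(roi, role)] = prior_from_points(
            roi, role, pts, membership_tolerance, point_radius
        )
    return ps


def centroid_distance(a: SpatialPrior, b: SpatialPrior) -> float:
    """Euclidean distance (mm) between two priors' centroids (same role)."""
    if a.role != b.role:
        raise PriorError(f"role mismatch: {a.role} vs {b.role}")
    return a.centroid.distance_to(b.centroid)


# --------------------------------------------------------------------------
# prospective validation


@dataclass(frozen=True)
class ThroughResult:
    entry_through: bool | None   # None when the ROI has no entry prior
    target_through: bool
    overall: bool


def through_prior(
    trajectory: Trajectory,
    priors: PriorSet,
    affine: AffineTransform,
    cortex: SurfaceMesh | None = None,
) -> ThroughResult:
    """Test whether a prospective trajectory passes through its ROI's priors.

    The overall verdict requires both entry and target membership; when the
    ROI has no entry prior the entry test is not applicable and the verdict
    is the target test alone.
    """
    if not priors.has(trajectory.roi, "target"):
        raise PriorError(f"ROI {trajectory.roi!r} has no target prior")
    t = to_template(trajectory, affine, cortex=cortex)
    target_pt = flip_to_canonical(t.target, t.side)
    target_through = priors.get(trajectory.roi, "target").contains(target_pt)
    if priors.has(trajectory.roi, "entry"):
        entry_pt = flip_to_canonical(t.entry, t.side)
        entry_through = priors.get(trajectory.roi, "entry").contains(entry_pt)
        return ThroughResult(entry_through, target_through, entry_through and target_through)
    return ThroughResult(None, target_through, target_through)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ValidationReport:
    """Per-ROI through/outside counts with integer percentages and totals."""

    rows: pd.DataFrame  # columns: region, n, through, outside, through_pct

    REPORT_COLUMNS = ["region", "n", "through", "outside", "through_pct"]

    @property
    def totals(self) -> dict:
        n = int(self.rows["n"].sum())
        through = int(self.rows["through"].sum())
        outside = int(self.rows["outside"].sum())
        return {
            "region": "total",
            "n": n,
            "through": through,
            "outside": outside,
            "through_pct": _round_half_up(100.0 * through / n) if n else 0,
        }

    def with_totals(self) -> pd.DataFrame:
        return pd.concat(
            [self.rows, pd.DataFrame([self.totals])], ignore_index=True
        )[self.REPORT_COLUMNS]

    def save_csv(self, path: str | Path) -> None:
        self.with_totals().to_csv(path, index=False)

    def to_json(self) -> dict:
        rows = self.rows.to_dict(orient="records")
        for r in rows:
            # exact rational alongside the printed integer percentage
            r["through_fraction"] = [int(r["through"]), int(r["n"])]
        return {"rows": rows, "totals": self.totals}

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))


def validate(
    test: TrajectorySet,
    priors: PriorSet,
    affines: Mapping[str, AffineTransform],
    cortex: SurfaceMesh | None = None,
    roi_order: Sequence[str] | None = None,
) -> ValidationReport:
    """Through-prior proportions of a prospective cohort, per ROI and total."""
    counts: dict[str, list[int]] = {}
    order: list[str] = list(roi_order) if roi_order else []
    for traj in test:
        if traj.patient_id not in affines:
            raise PriorError(f"no affine for patient {traj.patient_id!r}")
        res = through_prior(traj, priors, affines[traj.patient_id], cortex=cortex)
        if traj.roi not in counts:
            counts[traj.roi] = [0, 0]
            if traj.roi not in order:
                order.append(traj.roi)
        counts[traj.roi][0 if res.overall else 1] += 1
    rows = []
    for roi in order:
        if roi not in counts:
            continue
        through, outside = counts[roi]
        n = through + outside
        rows.append(
            dict(region=roi, n=n, through=through, outside=outside,
                 through_pct=_round_half_up(100.0 * through / n))
        )
    df = pd.DataFrame(rows, columns=ValidationReport.REPORT_COLUMNS)
    return ValidationReport(df)
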