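"""Per-trajectory planning criteria.

Implements the quantitative constraints a candidate electrode must satisfy:
the vessel-distance safety margin, the cumulative vascular risk score
sampled at 128 nodes along the trajectory, the gray-matter sampling ratio,
the intracerebral length, and the drilling angle relative to the surface
normal at the entry point.

The risk score models the width of the avascular corridor: each of 128
evenly spaced nodes contributes a risk that grows linearly from 0 (vessel
farther than ``d_max``, default 10 mm) to 1 (vessel at the safety margin),
and the cumulative score is the node mean. When any node comes closer to a
vessel than the margin, the score is lifted above 1 by the depth of the
breach, so "score > 1" is exactly equivalent to "some node breaches the
margin".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    GeometryError,
    Point3,
    SurfaceMesh,
    _points_segments_distance,
    ray_mesh_first_intersection,
    angle_from_surface_normal,
)
from .phantom import BinaryMask, VesselTree
from .trajectories import Trajectory

logger = logging.getLogger(__name__)

N_NODES = 128


@dataclass(frozen=True)
class ConstraintSettings:
    """Hard-constraint thresholds for candidate filtering.

    Defaults are the planning parameters used clinically: intracerebral
    length under 90 mm, drilling angle under 30 degrees from orthogonal,
    a 3 mm minimum vessel distance (risk score under 1), and over 10 mm
    between electrodes.
    """

    max_length: float = 90.0
    max_angle: float = 30.0
    margin: float = 3.0
    risk_threshold: float = 1.0
    min_electrode_spacing: float = 10.0
    d_max: float = 10.0

    def __post_init__(self) -> None:
        vals = (self.max_length, self.max_angle, self.margin,
                self.risk_threshold, self.min_electrode_spacing, self.d_max)
        if any(v <= 0 for v in vals):
            raise ValueError("all constraint settings must be positive")
        if self.margin >= self.d_max:
            raise ValueError("safety margin must be below the risk falloff distance d_max")


@dataclass(frozen=True)
class SafetyMarginInputs:
    electrode_radius: float
    implantation_errors: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.electrode_radius <= 0:
            raise ValueError("electrode radius must be positive")
        if any(e < 0 for e in self.implantation_errors):
            raise ValueError("implantation errors must be non-negative")


def safety_margin(inputs: SafetyMarginInputs, population_sd: bool = True) -> float:
    """Minimum permissible vessel distance (mm).

    electrode radius + mean implantation error + 3 * SD of the error.
    The SD is the population standard deviation unless ``population_sd`` is
    False (sample SD, ddof=1).
    """
    errors = np.asarray(inputs.implantation_errors, dtype=float)
    if errors.size == 0:
        raise ValueError(
            "no implantation errors supplied; pass an explicit margin instead"
        )
    ddof = 0 if population_sd else 1
    sd = float(errors.std(ddof=ddof)) if errors.size > ddof else 0.0
    return inputs.electrode_radius + float(errors.mean()) + 3.0 * sd


def sample_nodes(trajectory: Trajectory, n: int = N_NODES) -> np.ndarray:
    """n points evenly spaced from entry to target inclusive, as (n, 3)."""
    if n < 2:
        raise ValueError("need at least 2 nodes (entry and target)")
    e, t = trajectory.entry.as_array(), trajectory.target.as_array()
    frac = np.linspace(0.0, 1.0, n)[:, None]
    return e[None, :] * (1 - frac) + t[None, :] * frac


def vessel_surface_distance(p: Point3 | np.ndarray, vessels: VesselTree) -> float:
    """Distance (mm) from a point to the nearest vessel surface; 0 inside.

    +inf when the tree is empty (no vasculature to avoid).
    """
    return float(vessel_surface_distances(np.atleast_2d(
        p.as_array() if isinstance(p, Point3) else np.asarray(p, dtype=float)
    ), vessels)[0])


def vessel_surface_distances(pts: np.ndarray, vessels: VesselTree) -> np.ndarray:
    """Vectorised vessel-surface distances for (n, 3) points."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    a, b, r = vessels.arrays()
    if len(a) == 0:
        return np.full(len(pts), np.inf)
    axis_d = _points_segments_distance(pts, a, b)      # (n, m)
    return np.maximum(axis_d - r[None, :], 0.0).min(axis=1)


@dataclass
class RiskProfile:
    """128-node vascular risk profile of one trajectory."""

    node_points: np.ndarray       # (n, 3)
    node_distances: np.ndarray    # (n,) mm to nearest vessel surface
    node_risks: np.ndarray        # (n,) in [0, 1]
    cumulative_risk: float
    margin: float

    @property
    def min_distance(self) -> float:
        return float(self.node_distances.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": np.arange(len(self.node_distances)),
                "distance_mm": self.node_distances,
                "risk": self.node_risks,
            }
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def risk_score(
    trajectory: Trajectory,
    vessels: VesselTree,
    margin: float = 3.0,
    d_max: float = 10.0,
    n_nodes: int = N_NODES,
) -> RiskProfile:
    """Cumulative vascular risk of a trajectory.

    Node risk: clamp((d_max - d) / (d_max - margin), 0, 1). Cumulative risk
    is the node mean, replaced by 1 + (margin - min d) / margin whenever the
    closest node breaches the margin, so score > 1 iff the margin is
    breached. Scale-equivariant: scaling all geometry, margin and d_max by a
    common factor leaves the score unchanged.
    """
    if margin >= d_max:
        raise ValueError("margin must be below d_max")
    nodes = sample_nodes(trajectory, n_nodes)
    d = vessel_surface_distances(nodes, vessels)
    finite = np.where(np.isfinite(d), d, d_max)
    risks = np.clip((d_max - finite) / (d_max - margin), 0.0, 1.0)
    cumulative = float(risks.mean())
    dmin = float(d.min())
    if dmin < margin:
        cumulative = 1.0 + (margin - dmin) / margin
    return RiskProfile(nodes, d, risks, cumulative, margin)


def gray_matter_ratio(
    trajectory: Trajectory, gray_matter: BinaryMask, n_nodes: int = N_NODES
) -> float:
    """Fraction of the trajectory's sampled nodes lying in gray matter."""
    nodes = sample_nodes(trajectory, n_nodes)
    vox = gray_matter.world_to_voxel(nodes)
    shape = np.array(gray_matter.data.shape)
    in_grid = np.all((np.rint(vox) >= 0) & (np.rint(vox) < shape), axis=1)
    if not in_grid.any():
        logger.warning(
            "trajectory for ROI %r lies entirely outside the gray-matter grid",
            trajectory.roi,
        )
        return 0.0
    return float(gray_matter.contains(nodes).mean())


def intracerebral_length(trajectory: Trajectory, cortex: SurfaceMesh) -> float:
    """Distance (mm) from the cortical entry crossing to the target.

    The crossing is the first intersection of the entry->target ray with the
    cortex mesh; entry points already on the surface yield the full
    entry-target distance.
    """
    direction = trajectory.direction()
    origin = Point3.from_array(
        trajectory.entry.as_array() - 1e-3 * direction, trajectory.entry.space
    )
    hit = ray_mesh_first_intersection(origin, direction, cortex)
    if hit is None:
        raise GeometryError("trajectory does not intersect the cortex mesh")
    return hit.distance_to(trajectory.target)
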