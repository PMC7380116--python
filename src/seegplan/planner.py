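"""Candidate generation, hard-constraint filtering and plan assembly.

The planning loop mirrors the clinical workflow: sample entry/target point
pairs for each ROI in the implantation strategy, drop candidates violating
the hard constraints (length, drilling angle, critical structures, vascular
risk) recording the first failed constraint per rejection, optimise the
survivors for gray-matter sampling, present them risk-stratified (lowest
cumulative risk first), and greedily resolve inter-electrode conflicts in
strategy order so that implanted electrodes stay more than the minimum
spacing apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .geometry import (
    GeometryError,
    Point3,
    Segment3,
    SurfaceMesh,
    angle_from_surface_normal,
    segment_segment_distance,
)
from .metrics import (
    ConstraintSettings,
    RiskProfile,
    gray_matter_ratio,
    intracerebral_length,
    risk_score,
    sample_nodes,
)
from .phantom import LabeledRegion, Phantom
from .trajectories import Trajectory, TrajectorySet  # re-exported planning atoms

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "Strategy",
    "ScoredCandidate",
    "CandidateList",
    "PlanResult",
    "CandidatesExhausted",
    "generate_candidates",
    "filter_hard_constraints",
    "optimize_plan",
    "next_candidate",
]

REJECTION_ORDER = ("length", "angle", "critical", "risk")


class CandidatesExhausted(Exception):
    """No further candidate satisfies the requested iteration mode."""


@dataclass(frozen=True)
class Strategy:
    """Ordered implantation strategy: (target ROI, optional entry ROI) pairs."""

    items: tuple[tuple[str, str | None], ...]

    @classmethod
    def of(cls, *rois: str | tuple[str, str | None]) -> "Strategy":
        items = []
        for r in rois:
            items.append((r, None) if isinstance(r, str) else (r[0], r[1]))
        return cls(tuple(items))


@dataclass
class ScoredCandidate:
    """A candidate trajectory with all Table-style metrics attached."""

    trajectory: Trajectory
    risk: RiskProfile
    gm_ratio: float
    length: float
    angle: float

    @property
    def cumulative_risk(self) -> float:
        return self.risk.cumulative_risk

    def sort_key(self) -> tuple:
        # risk-stratified, gray-matter maximised, then shorter
        return (self.cumulative_risk, -self.gm_ratio, self.length)

    def metrics_dict(self) -> dict:
        e, t = self.trajectory.entry.as_array(), self.trajectory.target.as_array()
        return {
            "entry": e.tolist(),
            "target": t.tolist(),
            "roi": self.trajectory.roi,
            "cumulative_risk": self.cumulative_risk,
            "gm_ratio": self.gm_ratio,
            "length": self.length,
            "angle": self.angle,
        }


@dataclass
class CandidateList:
    """Risk-sorted surviving candidates plus a per-constraint rejection ledger."""

    survivors: list[ScoredCandidate]
    rejections: dict[str, int] = field(default_factory=dict)
    cursor: int = 0

    def __len__(self) -> int:
        return len(self.survivors)

    @property
    def current(self) -> ScoredCandidate:
        if not self.survivors:
            raise CandidatesExhausted("empty candidate list")
        return self.survivors[self.cursor]

    @property
    def head(self) -> ScoredCandidate:
        if not self.survivors:
            raise CandidatesExhausted("empty candidate list")
        return self.survivors[0]


def _sample_in_ball(rng: np.random.Generator, center: np.ndarray, radius: float, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, size=n) ** (1.0 / 3.0)
    return center[None, :] + v * r[:, None]


def _sample_surface(rng: np.random.Generator, mesh: SurfaceMesh, n: int) -> np.ndarray:
    tm = mesh.as_trimesh()
    areas = np.asarray(tm.area_faces, dtype=float)
    faces = rng.choice(len(areas), size=n, p=areas / areas.sum())
    tri = mesh.vertices[mesh.faces[faces]]
    # uniform barycentric sampling
    u, v = rng.uniform(size=n), rng.uniform(size=n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    w = 1 - u - v
    return tri[:, 0] * w[:, None] + tri[:, 1] * u[:, None] + tri[:, 2] * v[:, None]


def _sample_entry_points(
    rng: np.random.Generator,
    phantom: Phantom,
    entry_region: LabeledRegion | None,
    n: int,
    max_rounds: int = 200,
) -> np.ndarray:
    if entry_region is None:
        return _sample_surface(rng, phantom.cortex, n)
    collected: list[np.ndarray] = []
    for _ in range(max_rounds):
        pts = _sample_surface(rng, phantom.cortex, max(4 * n, 64))
        keep = pts[entry_region.contains(pts)]
        collected.append(keep)
        if sum(len(c) for c in collected) >= n:
            break
    pool = np.concatenate(collected) if collected else np.zeros((0, 3))
    if len(pool) < n:
        raise ValueError(
            f"entry region {entry_region.name!r} intersects too little cortex "
            f"to draw {n} surface points"
        )
    return pool[:n]


def generate_candidates(
    target_region: LabeledRegion,
    entry_region: LabeledRegion | None,
    phantom: Phantom,
    n_entry: int,
    n_target: int,
    seed: int,
) -> list[Trajectory]:
    """Cartesian pairing of sampled target points with sampled entry points.

    Targets are drawn uniformly in the target region; entries uniformly on
    the cortex surface, restricted to the entry region when one is given
    (the unconstrained case searches the whole cortex and hence can reach
    the global risk minimum for the target). Deterministic per seed.
    """
    if n_entry < 1 or n_target < 1:
        raise ValueError("need at least one entry and one target sample")
    rng = np.random.default_rng(seed)
    targets = _sample_in_ball(rng, target_region.center.as_array(), target_region.radius, n_target)
    entries = _sample_entry_points(rng, phantom, entry_region, n_entry)
    out: list[Trajectory] = []
    for t in targets:
        for e in entries:
            side = "right" if e[0] >= 0 else "left"
            out.append(
                Trajectory(
                    entry=Point3.from_array(e),
                    target=Point3.from_array(t),
                    roi=target_region.name,
                    side=side,
                    patient_id="plan",
                )
            )
    return out


def _hits_critical(trajectory: Trajectory, phantom: Phantom, n_nodes: int = 128) -> bool:
    if not phantom.critical:
        return False
    nodes = sample_nodes(trajectory, n_nodes)
    return any(region.contains(nodes).any() for region in phantom.critical)


def filter_hard_constraints(
    candidates: Sequence[Trajectory],
    phantom: Phantom,
    settings: ConstraintSettings | None = None,
) -> CandidateList:
    """Apply the hard constraints in order and risk-sort the survivors.

    Rejection order per candidate: intracerebral length >= max, drilling
    angle >= max, intersection with a critical structure, cumulative risk >=
    threshold (margin breach). Each rejection is attributed to the first
    failed constraint. Survivors are sorted by risk ascending, ties broken
    by higher gray-matter ratio then shorter length, which makes the result
    independent of input order.
    """
    settings = settings or ConstraintSettings()
    rejections = {k: 0 for k in REJECTION_ORDER}
    survivors: list[ScoredCandidate] = []
    for traj in candidates:
        try:
            length = intracerebral_length(traj, phantom.cortex)
        except GeometryError:
            rejections["length"] += 1
            continue
        if length >= settings.max_length:
            rejections["length"] += 1
            continue
        angle = angle_from_surface_normal(traj.entry, traj.direction(), phantom.cortex)
        if angle >= settings.max_angle:
            rejections["angle"] += 1
            continue
        if _hits_critical(traj, phantom):
            rejections["critical"] += 1
            continue
        profile = risk_score(traj, phantom.vessels, settings.margin, settings.d_max)
        if profile.cumulative_risk >= settings.risk_threshold:
            rejections["risk"] += 1
            continue
        gm = gray_matter_ratio(traj, phantom.gray_matter)
        survivors.append(ScoredCandidate(traj, profile, gm, length, angle))
    survivors.sort(key=ScoredCandidate.sort_key)
    return CandidateList(survivors, rejections)


def next_candidate(
    clist: CandidateList, mode: Literal["next_entry", "next_target"]
) -> Trajectory:
    """Advance the candidate cursor the way the interactive review does.

    ``next_entry`` moves to the next survivor (risk order) sharing the
    current candidate's target but with a different entry; ``next_target``
    is symmetric. Raises :class:`CandidatesExhausted` when no such candidate
    remains.
    """
    if mode not in ("next_entry", "next_target"):
        raise ValueError(f"unknown iteration mode {mode!r}")
    cur = clist.current.trajectory
    for i in range(clist.cursor + 1, len(clist.survivors)):
        cand = clist.survivors[i].trajectory
        same_target = np.allclose(cand.target.as_array(), cur.target.as_array())
        same_entry = np.allclose(cand.entry.as_array(), cur.entry.as_array())
        if mode == "next_entry" and same_target and not same_entry:
            clist.cursor = i
            return cand
        if mode == "next_target" and same_entry and not same_target:
            clist.cursor = i
            return cand
    raise CandidatesExhausted(f"no further {mode} candidate")


def _intracerebral_segment(cand: ScoredCandidate) -> Segment3:
    # entries are sampled on the cortex, so the intracerebral segment is the
    # full entry->target segment
    return cand.trajectory.segment()


@dataclass
class PlanResult:
    """Outcome of a multi-electrode plan: per-ROI lists plus the selection."""

    candidate_lists: dict[str, CandidateList]
    selected: dict[str, ScoredCandidate]
    ranks: dict[str, int]
    infeasible: list[str]

    def selected_trajectories(self) -> list[Trajectory]:
        return [c.trajectory for c in self.selected.values()]

    def to_json(self) -> dict:
        out: dict = {"rois": {}, "infeasible": self.infeasible}
        for roi, clist in self.candidate_lists.items():
            rec = {
                "n_survivors": len(clist),
                "rejections": clist.rejections,
                "candidates": [c.metrics_dict() for c in clist.survivors],
            }
            if roi in self.selected:
                rec["selected_rank"] = self.ranks[roi]
                rec["selected"] = self.selected[roi].metrics_dict()
            out["rois"][roi] = rec
        return out

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))


def optimize_plan(
    strategy: Strategy,
    phantom: Phantom,
    settings: ConstraintSettings | None = None,
    seed: int = 0,
    n_entry: int = 12,
    n_target: int = 5,
) -> PlanResult:
    """Plan every electrode in the strategy, resolving spacing conflicts.

    ROIs are processed in strategy order; for each, the lowest-risk
    surviving candidate whose minimum segment-to-segment distance to every
    already-selected electrode exceeds the spacing constraint is selected
    (advancing down the risk-sorted list as needed). An ROI with no feasible
    candidate is reported in ``infeasible`` rather than raising.
    """
    settings = settings or ConstraintSettings()
    lists: dict[str, CandidateList] = {}
    selected: dict[str, ScoredCandidate] = {}
    ranks: dict[str, int] = {}
    infeasible: list[str] = []
    rng = np.random.default_rng(seed)
    for target_roi, entry_roi in strategy.items:
        target_region = phantom.region(target_roi, "target")
        entry_region = phantom.region(entry_roi, "entry") if entry_roi else None
        cands = generate_candidates(
            target_region, entry_region, phantom, n_entry, n_target,
            seed=int(rng.integers(2**31)),
        )
        clist = filter_hard_constraints(cands, phantom, settings)
        lists[target_roi] = clist
        chosen: tuple[int, ScoredCandidate] | None = None
        for rank, cand in enumerate(clist.survivors):
            seg = _intracerebral_segment(cand)
            if all(
                segment_segment_distance(seg, _intracerebral_segment(other))
                > settings.min_electrode_spacing
                for other in selected.values()
            ):
                chosen = (rank, cand)
                break
        if chosen is None:
            infeasible.append(target_roi)
        else:
            ranks[target_roi], selected[target_roi] = chosen
    return PlanResult(lists, selected, ranks, infeasible)
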