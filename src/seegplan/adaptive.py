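"""Adaptive prior refinement with a K-nearest-neighbor classifier.

New implantations arrive in seeded folds; each fold's template-space entry
and target points are appended to the classifier's training data (k = 5,
uniform weights, Euclidean metric) and every prior's centroid, WCSS and
membership region are rebuilt from the augmented cloud. Ingestion is
append-only: no initial point is ever removed or relabeled, so the sequence
of states documents how institutional practice reshapes the priors.

Entry and target points are classified against separate candidate sets by
default (``role=`` restriction); the joint label space is available by
leaving the role unset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import TEMPLATE, AffineTransform, Point3
from .priors import (
    PriorRole,
    PriorSet,
    SpatialPrior,
    flip_to_canonical,
    prior_from_points,
    to_template,
)
from .trajectories import Trajectory, TrajectorySet

Label = tuple[str, str]  # (roi, role)


class AdaptiveError(ValueError):
    pass


@dataclass
class KnnPriorModel:
    """Labeled template-space points with a k=5 uniform Euclidean classifier.

    Fitting is storage only. Classification returns the majority label among
    the k nearest points; ties between labels are broken by the smaller mean
    neighbor distance, then lexicographically, and equal distances rank by
    insertion index — all deterministic.
    """

    points: np.ndarray                 # (n, 3)
    labels: list[Label]
    k: int = 5
    weighting: str = "uniform"
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = [tuple(l) for l in self.labels]  # type: ignore[misc]
        if len(self.points) != len(self.labels):
            raise AdaptiveError("points and labels length mismatch")
        if self.k < 1:
            raise AdaptiveError("k must be >= 1")
        if self.k > len(self.points):
            raise AdaptiveError(f"k={self.k} exceeds {len(self.points)} training points")

    def __len__(self) -> int:
        return len(self.points)

    def role_indices(self, role: str | None) -> np.ndarray:
        if role is None:
            return np.arange(len(self.points))
        return np.array([i for i, (_, r) in enumerate(self.labels) if r == role], dtype=int)

    def role_size(self, role: str) -> int:
        """Number of training points in one role's classifier."""
        return len(self.role_indices(role))

    def with_added(self, points: np.ndarray, labels: Sequence[Label]) -> "KnnPriorModel":
        pts = np.vstack([self.points, np.atleast_2d(points)])
        return KnnPriorModel(pts, self.labels + [tuple(l) for l in labels],
                             self.k, self.weighting, self.metric)

    def label_cloud(self, roi: str, role: str) -> np.ndarray:
        idx = [i for i, l in enumerate(self.labels) if l == (roi, role)]
        return self.points[idx]

    def to_json(self) -> dict:
        return {
            "points": self.points.tolist(),
            "labels": [list(l) for l in self.labels],
            "k": self.k,
            "weighting": self.weighting,
            "metric": self.metric,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "KnnPriorModel":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["points"], dtype=float),
                   [tuple(l) for l in obj["labels"]],
                   int(obj["k"]), obj.get("weighting", "uniform"),
                   obj.get("metric", "euclidean"))


def fit_knn(points: np.ndarray, labels: Sequence[Label], k: int = 5) -> KnnPriorModel:
    """Store labeled template points as a K-NN classifier (k=5 by default)."""
    return KnnPriorModel(np.asarray(points, dtype=float), list(labels), k=k)


def model_from_priors(priors: PriorSet, k: int = 5) -> KnnPriorModel:
    """Initialise the classifier from the point clouds of an existing prior set."""
    pts, labels = [], []
    for (roi, role), prior in sorted(priors.priors.items()):
        pts.append(prior.points)
        labels.extend([(roi, role)] * prior.n)
    if not pts:
        raise AdaptiveError("prior set is empty")
    return KnnPriorModel(np.vstack(pts), labels, k=k)


def _classify_one(
    model: KnnPriorModel, q: np.ndarray, idx: np.ndarray
) -> tuple[Label, dict[Label, int]]:
    d = np.linalg.norm(model.points[idx] - q[None, :], axis=1)
    k = min(model.k, len(idx))
    order = np.argsort(d, kind="stable")[:k]
    votes: dict[Label, int] = {}
    dists: dict[Label, list[float]] = {}
    for j in order:
        lab = model.labels[int(idx[j])]
        votes[lab] = votes.get(lab, 0) + 1
        dists.setdefault(lab, []).append(float(d[j]))
    top = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == top]
    winner = min(tied, key=lambda lab: (float(np.mean(dists[lab])), lab))
    return winner, votes


def classify(
    model: KnnPriorModel, p: Point3 | np.ndarray, role: str | None = None
) -> tuple[Label, dict[Label, int]]:
    """Majority label among the k nearest training points, with vote counts."""
    q = p.as_array() if isinstance(p, Point3) else np.asarray(p, dtype=float).reshape(3)
    idx = model.role_indices(role)
    if len(idx) == 0:
        raise AdaptiveError(f"no training points for role {role!r}")
    return _classify_one(model, q, idx)


def classify_batch(
    model: KnnPriorModel, pts: np.ndarray, role: str | None = None
) -> list[Label]:
    """Vectorised neighbor search + per-query deterministic vote."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    idx = model.role_indices(role)
    if len(idx) == 0:
        raise AdaptiveError(f"no training points for role {role!r}")
    return [_classify_one(model, q, idx)[0] for q in pts]


@dataclass(frozen=True)
class FoldSchedule:
    """Disjoint, exhaustive, (near-)equal seeded fold assignment."""

    assignments: tuple[tuple[int, ...], ...]
    seed: int

    @classmethod
    def make(cls, n_items: int, n_folds: int, seed: int) -> "FoldSchedule":
        if n_folds < 1:
            raise AdaptiveError("need at least one fold")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_items)
        base, extra = divmod(n_items, n_folds)
        folds, start = [], 0
        for i in range(n_folds):
            size = base + (1 if i < extra else 0)
            folds.append(tuple(int(j) for j in perm[start:start + size]))
            start += size
        return cls(tuple(folds), seed)

    def sizes(self) -> list[int]:
        return [len(f) for f in self.assignments]


@dataclass
class AdaptiveState:
    """Model + priors after ingesting ``fold_index`` folds (0 = initial)."""

    fold_index: int
    model: KnnPriorModel
    priors: PriorSet


def _canonical_role_points(
    traj: Trajectory, affine: AffineTransform | None
) -> dict[str, np.ndarray]:
    t = traj if affine is None else to_template(traj, affine)
    if t.space != TEMPLATE:
        raise AdaptiveError(
            "new trajectories must be in template space (or supply affines)"
        )
    return {
        "entry": flip_to_canonical(t.entry, t.side).as_array(),
        "target": flip_to_canonical(t.target, t.side).as_array(),
    }


def rebuild_priors(
    model: KnnPriorModel,
    template: str = "mni152-surrogate",
    min_count: int = 5,
    membership_tolerance: float = 2.0,
    point_radius: float = 5.0,
) -> PriorSet:
    """Recompute every prior from the model's current label clouds.

    Single source of truth: membership after ingestion uses the same rule as
    initial prior construction, applied to the augmented cloud.
    """
    ps = PriorSet(template=template)
    for label in sorted(set(model.labels)):
        roi, role = label
        cloud = model.label_cloud(roi, role)
        if len(cloud) < min_count:
            continue
        ps.priors[(roi, role)] = prior_from_points(
            roi, role, cloud, membership_tolerance, point_radius
        )
    return ps


def ingest_folds(
    initial: KnnPriorModel,
    initial_priors: PriorSet,
    new: TrajectorySet,
    n_folds: int = 5,
    seed: int = 0,
    affines: Mapping[str, AffineTransform] | None = None,
    min_count: int = 5,
    membership_tolerance: float = 2.0,
    point_radius: float = 5.0,
) -> list[AdaptiveState]:
    """Append new implantations fold by fold and re-derive the priors.

    Returns n_folds + 1 states: the initial one, then one per ingested fold.
    Fold membership is a seeded uniform random partition into equal groups
    (sizes differ by at most one). Each trajectory contributes its canonical
    template-space entry and target point under its ROI label.
    """
    states = [AdaptiveState(0, initial, initial_priors)]
    trajs = list(new)
    if not trajs:
        return states
    schedule = FoldSchedule.make(len(trajs), n_folds, seed)
    model = initial
    for fold_i, fold in enumerate(schedule.assignments, start=1):
        pts, labels = [], []
        for j in fold:
            traj = trajs[j]
            aff = affines.get(traj.patient_id) if affines is not None else None
            role_pts = _canonical_role_points(traj, aff)
            for role in ("entry", "target"):
                pts.append(role_pts[role])
                labels.append((traj.roi, role))
        model = model.with_added(np.array(pts), labels)
        priors = rebuild_priors(
            model, template=initial_priors.template,
            min_count=min_count, membership_tolerance=membership_tolerance,
            point_radius=point_radius,
        )
        states.append(AdaptiveState(fold_i, model, priors))
    return states


def decision_region_volume(
    model: KnnPriorModel,
    roi: str,
    role: str,
    box_min: np.ndarray,
    box_max: np.ndarray,
    step: float,
    restrict_role: bool = True,
) -> float:
    """Grid-sampled volume (mm^3) of space the classifier assigns to a label.

    Samples the bounding box on a regular grid of spacing ``step`` and sums
    voxel volumes whose centers classify as (roi, role). Restricted to the
    same-role candidate set by default (separate entry/target classifiers).
    """
    if step <= 0:
        raise AdaptiveError("grid step must be positive")
    box_min = np.asarray(box_min, dtype=float)
    box_max = np.asarray(box_max, dtype=float)
    axes = [np.arange(lo + step / 2, hi, step) for lo, hi in zip(box_min, box_max)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    labels = classify_batch(model, grid, role=role if restrict_role else None)
    hits = sum(1 for l in labels if l == (roi, role))
    return hits * step**3
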