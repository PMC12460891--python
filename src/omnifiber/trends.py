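"""Soft clustering of temporal abundance profiles into tendencies.

Each region's stage-mean profiles (6 time points) are z-scored per feature
and clustered with fuzzy c-means (the algorithm behind Mfuzz-style
time-course clustering): memberships

    u_ij = 1 / sum_k (||x_i - v_j|| / ||x_i - v_k||)^(2/(m-1))

and centers

    v_j = sum_i u_ij^m x_i / sum_i u_ij^m

are alternated until the objective sum_ij u_ij^m ||x_i - v_j||^2 stabilizes.
The fuzzifier m controls how soft the partition is (m -> 1 recovers
k-means); c = 4 tendencies is the default. Cluster indices are relabeled
canonically by center shape — ordered by the stage at which the center
peaks, then by its value at the final stage — so "Tendency k" is comparable
across regions and runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, StudyDesign, log2_transform, stage_mean_profiles

__all__ = [
    "FcmModel",
    "TrendAssignment",
    "TrendOverlap",
    "standardize_profiles",
    "fuzzy_cmeans",
    "assign_tendencies",
    "compare_regions",
    "region_trends",
]

logger = logging.getLogger(__name__)


@dataclass
class FcmModel:
    """A fitted fuzzy c-means model."""

    centers: np.ndarray  # c x T
    membership: np.ndarray  # features x c, rows sum to 1
    fuzzifier_m: float
    objective: float
    n_iter: int
    seed: int
    feature_ids: list[str] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)


@dataclass
class TrendAssignment:
    feature_id: str
    region: str
    tendency: int  # 1..c after canonical relabeling; 0 = unassigned
    max_membership: float


@dataclass
class TrendOverlap:
    """Cross-region composition of one tendency."""

    tendency: int
    n_shared: int
    n_ld_only: int
    n_sd_only: int

    @property
    def frac_different(self) -> float:
        total = self.n_shared + self.n_ld_only + self.n_sd_only
        if total == 0:
            raise ZeroDivisionError("empty tendency has no composition")
        return (self.n_ld_only + self.n_sd_only) / total


def standardize_profiles(stage_means: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-score across stages (mean 0, sample sd 1).

    Features with zero temporal variance carry no shape information and are
    excluded (logged).
    """
    if stage_means.n_samples < 2:
        raise ValueError("need at least 2 stages to standardize profiles")
    X = stage_means.data
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("standardize_profiles: excluded %d constant features", n_dropped)
    X = X.loc[keep]
    sd = sd.loc[keep]
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(Z, modality=stage_means.modality, scale=stage_means.scale)


def _kmeanspp_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding of c initial centers from the data rows."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(c - 1):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float)


def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # n x c
    zero = d2 <= 0
    U = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-power)
        U = inv / inv.sum(axis=1, keepdims=True)
    # exact-zero distance: full membership on the coincident center(s)
    rows = zero.any(axis=1)
    if rows.any():
        U[rows] = 0.0
        U[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return U


def fuzzy_cmeans(
    X: np.ndarray,
    c: int = 4,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> FcmModel:
    """Fit fuzzy c-means by alternating membership/center updates.

    ``X`` is a features x timepoints array (typically standardized
    profiles). Deterministic given ``seed``; initialization is k-means++
    style center seeding. Stops when the objective changes by less than
    ``tol`` or after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")
    n = X.shape[0]
    if c < 1:
        raise ValueError("c must be >= 1")
    if c >= n:
        raise ValueError(f"c = {c} must be smaller than the number of features ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)

    if c == 1:
        center = X.mean(axis=0, keepdims=True)
        U = np.ones((n, 1))
        obj = float(((X - center) ** 2).sum())
        return FcmModel(center, U, m, obj, 0, seed, feature_ids or [], [obj])

    centers = _kmeanspp_init(X, c, rng)
    history: list[float] = []
    prev = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        U = _memberships(X, centers, m)
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = float((Um * d2).sum())
        history.append(obj)
        if abs(prev - obj) < tol:
            break
        prev = obj
    U = _memberships(X, centers, m)
    return FcmModel(
        centers=centers,
        membership=U,
        fuzzifier_m=m,
        objective=history[-1],
        n_iter=n_iter,
        seed=seed,
        feature_ids=list(feature_ids) if feature_ids is not None else [],
        objective_history=history,
    )


def canonical_cluster_order(centers: np.ndarray) -> np.ndarray:
    """Permutation ordering clusters by (stage of center max, value at final stage).

    ``order[k]`` is the raw cluster index that becomes Tendency k+1.
    """
    keys = [(int(np.argmax(v)), float(v[-1]), j) for j, v in enumerate(centers)]
    return np.array([j for _, _, j in sorted(keys)], dtype=int)


def assign_tendencies(
    model: FcmModel,
    min_membership: float = 0.0,
    region: str = "",
    feature_ids: list[str] | None = None,
) -> list[TrendAssignment]:
    """Hard tendency labels by argmax membership, canonically relabeled.

    Features whose maximum membership falls below ``min_membership`` are
    labeled tendency 0 (unassigned). Argmax ties break toward the lowest
    raw cluster index.
    """
    ids = feature_ids if feature_ids is not None else model.feature_ids
    if len(ids) != model.membership.shape[0]:
        raise ValueError("feature_ids length does not match membership rows")
    order = canonical_cluster_order(model.centers)
    # rank[j] = tendency number (1-based) of raw cluster j
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    hard = model.membership.argmax(axis=1)
    maxu = model.membership.max(axis=1)
    out = []
    for i, fid in enumerate(ids):
        tendency = int(rank[hard[i]]) if maxu[i] >= min_membership else 0
        out.append(
            TrendAssignment(
                feature_id=fid,
                region=region,
                tendency=tendency,
                max_membership=float(maxu[i]),
            )
        )
    return out


def compare_regions(
    ld: list[TrendAssignment], sd: list[TrendAssignment]
) -> list[TrendOverlap]:
    """Shared vs region-unique feature composition per tendency."""
    ld_by = {}
    sd_by = {}
    for a in ld:
        if a.tendency > 0:
            ld_by.setdefault(a.tendency, set()).add(a.feature_id)
    for a in sd:
        if a.tendency > 0:
            sd_by.setdefault(a.tendency, set()).add(a.feature_id)
    out = []
    for t in sorted(set(ld_by) | set(sd_by)):
        l = ld_by.get(t, set())
        s = sd_by.get(t, set())
        out.append(
            TrendOverlap(
                tendency=t,
                n_shared=len(l & s),
                n_ld_only=len(l - s),
                n_sd_only=len(s - l),
            )
        )
    return out


def region_trends(
    mp: ExpressionMatrix,
    d: StudyDesign,
    region: str,
    c: int = 4,
    m: float = 2.0,
    seed: int = 0,
    min_membership: float = 0.0,
) -> tuple[FcmModel, list[TrendAssignment]]:
    """Convenience pipeline: stage means -> z-score -> FCM -> tendencies.

    Accepts a linear-scale matrix (log2(x+1) is applied first) restricted to
    one region's samples.
    """
    sub = mp.subset_samples([s for s in d.samples_for(region=region) if s in mp.data.columns])
    logm = log2_transform(sub) if sub.scale == "linear" else sub
    sub_design = StudyDesign(
        d.table[d.table["region"] == region].copy(), stages=d.stages, regions=d.regions
    )
    profiles = stage_mean_profiles(logm, sub_design, pool_regions=True)
    Z = standardize_profiles(profiles)
    model = fuzzy_cmeans(Z.values, c=c, m=m, seed=seed, feature_ids=Z.feature_ids)
    assignments = assign_tendencies(model, min_membership=min_membership, region=region)
    return model, assignments
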