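"""Cross-dataset expression harmonization for ortholog comparisons.

Combining expression of single-copy ortholog groups across datasets
(different species, platforms, studies) requires removing dataset-level
batch effects while protecting biological covariates. The adjustment here
is a location-scale fit: per feature, an additive model

    value = grand mean + covariate effects + batch shift + residual

is estimated by least squares; batch shifts are removed and residuals are
rescaled from their per-batch spread to the pooled spread. Covariate
effects are retained untouched. (This is a plain non-empirical-Bayes
location-scale adjustment — a deliberate simplification of
shrinkage-based batch correction with a directly testable contract:
equalized batch moments, preserved covariate contrasts.)

After adjustment, rows are z-scored and clustered (k-means) to obtain
cross-species expression pattern clusters C1..Ck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "batch_adjust",
    "zscore_rows",
    "cluster_profiles",
    "ClusterResult",
    "read_ortholog_table",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _design_from_covariates(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    """Intercept + dummy-coded covariates (reference level dropped)."""
    design = pd.DataFrame({"intercept": 1.0}, index=index)
    if covariates is not None:
        cov = covariates.loc[index]
        for col in cov.columns:
            if pd.api.types.is_numeric_dtype(cov[col]):
                design[col] = cov[col].astype(float)
            else:
                dummies = pd.get_dummies(cov[col], prefix=col, drop_first=True)
                for dc in dummies.columns:
                    design[dc] = dummies[dc].astype(float)
    return design


def batch_adjust(
    x: pd.DataFrame,
    batch: pd.Series | Mapping[str, str],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Remove batch location/scale effects from a features x samples table.

    ``x`` holds log-scale values; ``batch`` maps each sample (column) to its
    batch label; ``covariates`` (samples x columns) holds protected effects
    such as region or breed. Raises if any batch has < 2 samples or if a
    batch dummy is linearly aliased with the covariate design.
    """
    batch = pd.Series(dict(batch) if not isinstance(batch, pd.Series) else batch)
    missing = [s for s in x.columns if s not in batch.index]
    if missing:
        raise ValueError(f"samples without batch labels: {missing[:5]}")
    batch = batch.loc[x.columns]
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        return x.copy()
    counts = batch.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        raise ValueError(f"batches with < 2 samples cannot be adjusted: {small}")

    C = _design_from_covariates(covariates, x.columns)
    B = pd.get_dummies(batch, prefix="batch", drop_first=True).astype(float)
    B = B.loc[x.columns]

    # rank check: every batch dummy must add a dimension beyond the covariates
    rank_c = np.linalg.matrix_rank(C.to_numpy())
    aliased = []
    for col in B.columns:
        combined = np.column_stack([C.to_numpy(), B[[col]].to_numpy()])
        if np.linalg.matrix_rank(combined) == rank_c:
            aliased.append(col)
    if aliased:
        raise ValueError(f"batch confounded with covariates; aliased columns: {aliased}")

    D = np.column_stack([C.to_numpy(), B.to_numpy()])
    Y = x.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    n_cov = C.shape[1]
    batch_effect = B.to_numpy() @ beta[n_cov:]
    fitted = D @ beta
    resid = Y - fitted

    # per-batch residual scale -> pooled scale
    pooled_sd = resid.std(axis=0, ddof=1)
    adjusted_resid = resid.copy()
    for level in levels:
        rows = (batch == level).to_numpy()
        sd_b = resid[rows].std(axis=0, ddof=1)
        factor = np.where(sd_b > _EPS, pooled_sd / np.maximum(sd_b, _EPS), 1.0)
        adjusted_resid[rows] = resid[rows] * factor

    out = (fitted - batch_effect) + adjusted_resid
    return pd.DataFrame(out.T, index=x.index, columns=x.columns)


def zscore_rows(x: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-feature z-score (mean 0, sample sd 1) across samples.

    Zero-variance rows are dropped; returns (standardized table, number of
    dropped rows).
    """
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("zscore_rows: dropped %d zero-variance rows", n_dropped)
    z = x.loc[keep].sub(x.loc[keep].mean(axis=1), axis=0).div(sd.loc[keep], axis=0)
    return z, n_dropped


@dataclass
class ClusterResult:
    """Hard profile clusters C1..Ck with per-group mean trajectories."""

    labels: pd.Series  # feature -> "C1".."Ck"
    centers: pd.DataFrame  # cluster x columns
    group_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def members(self, cluster: str) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def cluster_profiles(
    x: pd.DataFrame,
    k: int,
    seed: int = 0,
    column_groups: Mapping[str, str] | None = None,
) -> ClusterResult:
    """k-means clustering of standardized feature profiles.

    ``column_groups`` maps sample columns to a group label (e.g. species);
    when given, per-cluster mean trajectories are computed within each group
    (columns kept in input order). Cluster names C1..Ck are assigned in
    decreasing cluster-size order for stable reporting.
    """
    if k >= x.shape[0]:
        raise ValueError(f"k = {k} must be smaller than the number of rows ({x.shape[0]})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(x.to_numpy(dtype=float))
    # name clusters by decreasing size (ties by raw index)
    sizes = pd.Series(raw).value_counts()
    order = sorted(range(k), key=lambda j: (-sizes.get(j, 0), j))
    name_of = {j: f"C{i + 1}" for i, j in enumerate(order)}
    labels = pd.Series([name_of[j] for j in raw], index=x.index, name="cluster")
    centers = pd.DataFrame(
        km.cluster_centers_[order], index=[f"C{i + 1}" for i in range(k)], columns=x.columns
    )
    group_curves: dict[str, pd.DataFrame] = {}
    if column_groups is not None:
        for group in dict.fromkeys(column_groups.values()):
            cols = [c for c in x.columns if column_groups.get(c) == group]
            curves = pd.DataFrame(
                {
                    name: x.loc[labels == name, cols].mean(axis=0)
                    for name in centers.index
                }
            ).T
            group_curves[group] = curves
    return ClusterResult(labels=labels, centers=centers, group_curves=group_curves)


def read_ortholog_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a long-format ortholog expression table.

    Columns: gene_group, dataset, sample, value (tab-separated). Returns a
    wide features x samples table plus the sample -> dataset batch labels.
    """
    long = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_group", "dataset", "sample", "value"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    wide = long.pivot_table(index="gene_group", columns="sample", values="value")
    batch = long.drop_duplicates("sample").set_index("sample")["dataset"]
    return wide, batch.loc[wide.columns]
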