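"""Global summaries shared by all analysis stages: stage correlations and PCA."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix, StudyDesign, stage_mean_profiles

__all__ = ["StageCorrelationMatrix", "PcaResult", "stage_correlations", "run_pca"]

logger = logging.getLogger(__name__)


@dataclass
class StageCorrelationMatrix:
    """Pearson correlations between stage-mean expression profiles."""

    stages: list[str]
    r: pd.DataFrame  # symmetric, unit diagonal

    def adjacent_values(self) -> list[float]:
        """Correlations between chronologically adjacent stages."""
        return [
            float(self.r.loc[a, b]) for a, b in zip(self.stages[:-1], self.stages[1:])
        ]


@dataclass
class PcaResult:
    """Sample scores on principal axes plus per-component variance fractions."""

    scores: pd.DataFrame  # samples x components
    explained_fraction: np.ndarray


def stage_correlations(
    m: ExpressionMatrix, d: StudyDesign, pool_regions: bool = True
) -> StageCorrelationMatrix:
    """Pearson correlation between stage-mean feature profiles for all stage pairs.

    The matrix must be on the log2 scale. Features with zero variance across
    the stage-mean profiles (globally constant) carry no correlation signal
    and are excluded; non-finite values are excluded pairwise.
    """
    if m.scale != "log2":
        raise ValueError("stage_correlations expects a log2-scale matrix")
    profiles = stage_mean_profiles(m, d, pool_regions=pool_regions)
    X = profiles.data
    variable = X.std(axis=1, ddof=0) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info("stage_correlations: excluded %d zero-variance features", n_dropped)
    X = X.loc[variable]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 usable features for stage correlations")
    stages = list(d.stages) if pool_regions else list(X.columns)
    r = pd.DataFrame(np.eye(len(X.columns)), index=X.columns, columns=X.columns)
    for i, a in enumerate(X.columns):
        for b in X.columns[i + 1 :]:
            pair = X[[a, b]].to_numpy()
            ok = np.isfinite(pair).all(axis=1)
            va, vb = pair[ok, 0], pair[ok, 1]
            if len(va) < 2 or va.std() == 0 or vb.std() == 0:
                raise ValueError(f"cannot correlate stages {a!r} and {b!r}")
            rho = float(np.corrcoef(va, vb)[0, 1])
            r.loc[a, b] = r.loc[b, a] = rho
    return StageCorrelationMatrix(stages=stages, r=r)


def run_pca(
    m: ExpressionMatrix, n_components: int, scale_features: bool = False
) -> PcaResult:
    """Project samples onto the principal axes of the feature-centered data.

    Features (variables) are centered, and optionally unit-scaled with
    ``scale_features=True``; samples are the observations. The sign of each
    component is fixed so that its largest-magnitude feature loading is
    positive, making scores reproducible across runs.
    """
    if m.scale != "log2":
        raise ValueError("run_pca expects a log2-scale matrix")
    if n_components < 1 or n_components > min(m.n_features, m.n_samples):
        raise ValueError("n_components out of range")
    X = m.values.T  # samples x features
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("matrix is constant; PCA undefined")
    if scale_features:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        explained_fraction=pca.explained_variance_ratio_.copy(),
    )
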