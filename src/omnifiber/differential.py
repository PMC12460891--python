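"""Two-group differential testing and the calling policies used in the study.

Four built-in policies mirror how differentially abundant proteins (DAPs)
and differentially expressed genes (DEGs) were defined:

==============  =============================  ==========  =====
policy          fold-change gate (linear)      p used      alpha
==============  =============================  ==========  =====
``region_dap``  >= 1.2 or <= 0.833             raw         0.05
``stage_dap``   none                           BH-adjusted 0.05
``stage_deg``   >= 2 or <= 0.5 (|log2FC| >= 1) BH-adjusted 0.05
``region_deg``  >= 2 or <= 0.5                 raw         0.05
==============  =============================  ==========  =====

Regional contrasts use raw p-values because region differences are subtle
and FDR correction would leave few calls; stage contrasts use BH-adjusted
p-values. Fold change is the ratio of linear-scale group means; the t test
runs on log2(x+1) values. Protein zeros (not detected) are excluded from
testing, and features with fewer than two detected replicates in either
group are skipped rather than imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, StudyDesign

__all__ = [
    "CallingPolicy",
    "POLICIES",
    "ContrastSpec",
    "DifferentialRecord",
    "TestResult",
    "two_group_test",
    "bh_adjust",
    "call_contrast",
    "enumerate_stage_contrasts",
    "summarize_dap_sets",
    "DapSetSummary",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallingPolicy:
    """Thresholds that turn (fold change, p) into a differential call.

    ``fc_low``/``fc_high`` bound the linear fold-change gate (inclusive);
    both None disables the gate. ``use_adjusted_p`` selects BH-adjusted q
    versus raw p, compared strictly against ``alpha``.
    """

    name: str
    fc_low: float | None
    fc_high: float | None
    use_adjusted_p: bool
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.fc_low is None) != (self.fc_high is None):
            raise ValueError("fc_low and fc_high must both be set or both be None")
        if self.fc_low is not None and not (self.fc_low < 1 < self.fc_high):
            raise ValueError("need fc_low < 1 < fc_high")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def passes_fc(self, fc_linear: float) -> bool:
        if self.fc_low is None:
            return True
        return fc_linear >= self.fc_high or fc_linear <= self.fc_low

    def passes_p(self, p: float, q: float) -> bool:
        return (q if self.use_adjusted_p else p) < self.alpha


POLICIES: dict[str, CallingPolicy] = {
    "region_dap": CallingPolicy("region_dap", 0.833, 1.2, use_adjusted_p=False),
    "stage_dap": CallingPolicy("stage_dap", None, None, use_adjusted_p=True),
    "stage_deg": CallingPolicy("stage_deg", 0.5, 2.0, use_adjusted_p=True),
    "region_deg": CallingPolicy("region_deg", 0.5, 2.0, use_adjusted_p=False),
}


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison: (region, stage) selectors for groups A and B.

    A selector component of None means "all". ``region_within_stage``
    compares the two regions at one stage; ``stage_pair_within_region``
    compares two stages within one region.
    """

    axis: str  # "region_within_stage" | "stage_pair_within_region"
    group_a: tuple[str | None, str | None]  # (region, stage)
    group_b: tuple[str | None, str | None]

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    @property
    def label(self) -> str:
        def fmt(g: tuple[str | None, str | None]) -> str:
            return ":".join(x for x in g if x is not None) or "all"

        return f"{fmt(self.group_a)}_vs_{fmt(self.group_b)}"


@dataclass
class TestResult:
    log2fc: float
    p_value: float
    degenerate: bool = False


@dataclass
class DifferentialRecord:
    """Per-feature result of one contrast under one calling policy."""

    feature_id: str
    fc_linear: float
    log2fc: float
    p_value: float
    q_value: float
    n_a: int
    n_b: int
    called: bool
    policy: str
    contrast: str = ""


def _ttest_from_moments(
    mean_a: np.ndarray,
    var_a: np.ndarray,
    n_a: np.ndarray,
    mean_b: np.ndarray,
    var_b: np.ndarray,
    n_b: np.ndarray,
    variant: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided t test from group moments (sample variances, ddof=1).

    Degenerate features (both group variances zero) get p = 1 when the means
    agree and p = 0 otherwise.
    """
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "student":
            df = n_a + n_b - 2
            sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
            se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        elif variant == "welch":
            va_n, vb_n = var_a / n_a, var_b / n_b
            se = np.sqrt(va_n + vb_n)
            df = (va_n + vb_n) ** 2 / (
                va_n**2 / (n_a - 1) + vb_n**2 / (n_b - 1)
            )
        else:
            raise ValueError(f"unknown t-test variant {variant!r}")
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = (var_a == 0) & (var_b == 0)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return p, degenerate


def two_group_test(
    a: Sequence[float], b: Sequence[float], variant: str = "student"
) -> TestResult:
    """Two-sided t test of two log2-scale groups.

    Returns the mean difference (log2 fold change on the test scale) and the
    two-sided p-value. When both groups are constant: p = 1 if they are
    equal, p = 0 (flagged degenerate) otherwise.
    """
    a = np.asarray([x for x in a if np.isfinite(x)], dtype=float)
    b = np.asarray([x for x in b if np.isfinite(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 usable values per group")
    p, degen = _ttest_from_moments(
        np.array([a.mean()]),
        np.array([a.var(ddof=1)]),
        np.array([len(a)], dtype=float),
        np.array([b.mean()]),
        np.array([b.var(ddof=1)]),
        np.array([len(b)], dtype=float),
        variant,
    )
    return TestResult(
        log2fc=float(a.mean() - b.mean()),
        p_value=float(p[0]),
        degenerate=bool(degen[0] and a.mean() != b.mean()),
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_group(
    d: StudyDesign, selector: tuple[str | None, str | None]
) -> list[str]:
    region, stage = selector
    return d.samples_for(region=region, stage=stage)


def call_contrast(
    mp: ExpressionMatrix,
    d: StudyDesign,
    contrast: ContrastSpec,
    policy: CallingPolicy,
    variant: str = "student",
    pseudocount: float = 1.0,
) -> list[DifferentialRecord]:
    """Test every feature in one contrast and apply a calling policy.

    The matrix must be linear scale. Fold change is the ratio of linear
    group means; the t test uses log2(x + pseudocount). For protein
    matrices, zeros are "not detected" and are excluded from both the means
    and the test; features with < 2 detected values in either group are
    skipped (logged, not imputed). BH q-values are computed over the
    features tested in this contrast.
    """
    if mp.scale != "linear":
        raise ValueError("call_contrast expects a linear-scale matrix")
    d.validate_against(mp)
    samples_a = [s for s in _resolve_group(d, contrast.group_a) if s in mp.data.columns]
    samples_b = [s for s in _resolve_group(d, contrast.group_b) if s in mp.data.columns]
    if not samples_a or not samples_b:
        raise ValueError(f"contrast {contrast.label} resolves to an empty group")

    A = mp.data[samples_a].to_numpy(dtype=float)
    B = mp.data[samples_b].to_numpy(dtype=float)
    if mp.modality == "protein":
        A = np.where(A == 0, np.nan, A)
        B = np.where(B == 0, np.nan, B)
    n_a = np.isfinite(A).sum(axis=1).astype(float)
    n_b = np.isfinite(B).sum(axis=1).astype(float)
    testable = (n_a >= 2) & (n_b >= 2)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info(
            "contrast %s: skipped %d features with < 2 detected replicates",
            contrast.label,
            n_skipped,
        )

    idx = np.flatnonzero(testable)
    At, Bt = A[idx], B[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a_lin = np.nanmean(At, axis=1)
        mean_b_lin = np.nanmean(Bt, axis=1)
        fc_linear_t = mean_a_lin / mean_b_lin
        La = np.log2(np.where(np.isfinite(At), At, np.nan) + pseudocount)
        Lb = np.log2(np.where(np.isfinite(Bt), Bt, np.nan) + pseudocount)
        mean_a = np.nanmean(La, axis=1)
        mean_b = np.nanmean(Lb, axis=1)
        var_a = np.nanvar(La, axis=1, ddof=1)
        var_b = np.nanvar(Lb, axis=1, ddof=1)
    fc_linear = np.full(A.shape[0], np.nan)
    fc_linear[idx] = fc_linear_t
    p, _ = _ttest_from_moments(
        mean_a, var_a, n_a[idx], mean_b, var_b, n_b[idx], variant
    )
    q = bh_adjust(p)

    records: list[DifferentialRecord] = []
    feature_ids = mp.feature_ids
    for j, i in enumerate(idx):
        fc = float(fc_linear[i])
        with np.errstate(divide="ignore"):
            log2fc = float(np.log2(fc)) if fc > 0 else -np.inf
        called = policy.passes_fc(fc) and policy.passes_p(float(p[j]), float(q[j]))
        records.append(
            DifferentialRecord(
                feature_id=feature_ids[i],
                fc_linear=fc,
                log2fc=log2fc,
                p_value=float(p[j]),
                q_value=float(q[j]),
                n_a=int(n_a[i]),
                n_b=int(n_b[i]),
                called=bool(called),
                policy=policy.name,
                contrast=contrast.label,
            )
        )
    return records


def enumerate_stage_contrasts(
    d: StudyDesign, scope: str = "adjacent"
) -> list[ContrastSpec]:
    """All within-region stage contrasts, region-major, earlier stage first.

    ``scope="adjacent"`` yields the 5 consecutive transitions per region;
    ``scope="all_pairs"`` yields all C(n_stages, 2) pairs per region.
    """
    if scope == "adjacent":
        pairs = list(zip(d.stages[:-1], d.stages[1:]))
    elif scope == "all_pairs":
        pairs = list(itertools.combinations(d.stages, 2))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = []
    for region in d.regions:
        present = set(d.table.loc[d.table["region"] == region, "stage"])
        for s1, s2 in pairs:
            if s1 in present and s2 in present:
                out.append(
                    ContrastSpec(
                        axis="stage_pair_within_region",
                        group_a=(region, s1),
                        group_b=(region, s2),
                    )
                )
    return out


@dataclass
class DapSetSummary:
    """Set-level view of called features across contrasts (UpSet-style)."""

    sizes: dict[str, int]
    union_size: int
    pairwise_intersections: pd.DataFrame
    upset_counts: dict[frozenset, int]
    stage_shares: dict[str, float] = field(default_factory=dict)


def summarize_dap_sets(
    called_sets: Mapping[str, set],
    stage_of: Mapping[str, str] | None = None,
) -> DapSetSummary:
    """Intersection structure of per-contrast called sets.

    ``upset_counts`` maps each exact membership pattern (the frozenset of
    contrast names a feature is called in) to the number of features with
    that pattern. With ``stage_of`` (contrast name -> stage group), per-stage
    shares count each called feature once per stage group it appears in,
    normalized so shares sum to 1.
    """
    if not called_sets:
        raise ValueError("need at least one contrast")
    names = list(called_sets)
    union: set = set().union(*called_sets.values())
    inter = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            inter.loc[a, b] = len(called_sets[a] & called_sets[b])
    upset: dict[frozenset, int] = {}
    for feat in union:
        pattern = frozenset(n for n in names if feat in called_sets[n])
        upset[pattern] = upset.get(pattern, 0) + 1
    shares: dict[str, float] = {}
    if stage_of is not None:
        by_stage: dict[str, set] = {}
        for name, members in called_sets.items():
            stage = stage_of[name]
            by_stage.setdefault(stage, set()).update(members)
        total = sum(len(v) for v in by_stage.values())
        if total:
            shares = {stage: len(v) / total for stage, v in by_stage.items()}
    return DapSetSummary(
        sizes={n: len(s) for n, s in called_sets.items()},
        union_size=len(union),
        pairwise_intersections=inter,
        upset_counts=upset,
        stage_shares=shares,
    )


def records_to_frame(records: Iterable[DifferentialRecord]) -> pd.DataFrame:
    """Flatten differential records into the standard output table."""
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "feature_id": r.feature_id,
                "fc_linear": r.fc_linear,
                "log2fc": r.log2fc,
                "p": r.p_value,
                "q": r.q_value,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "called": r.called,
                "policy": r.policy,
            }
            for r in records
        ]
    )
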