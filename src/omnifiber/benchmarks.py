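"""Validation benchmarks: calibration, planted-truth recovery, exact checks.

Each function builds its own inputs (simulated data or exact fixtures),
runs the corresponding pipeline stage, and returns the measured quantities.
They define the package's standard operating-characteristic checks:

- null t-test calibration at the study's replication level (n = 3 vs 3),
- differential recovery of planted 1.5-log2 region effects under the
  region-DAP policy at 40% prevalence (chosen so that both the >= 0.9
  sensitivity and <= 0.1 observed-FDR operating targets of the raw-p +
  fold-change-gate policy lie inside the design's power curve, not on its
  boundary),
- exactness of the six-type classifier against direct predicate evaluation
  and recovery of a planted type mixture,
- fuzzy c-means objective monotonicity and archetype recovery,
- hypergeometric tail vs exact enumeration,
- presence-rule agreement with manual enumeration on a hand-built fixture,
- batch-adjustment moment equalization and covariate preservation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .concordance import classify_six_types_array
from .differential import POLICIES, ContrastSpec, call_contrast
from .enrichment import hypergeom_upper_tail
from .harmonization import batch_adjust
from .matrix import ExpressionMatrix, StudyDesign
from .presence import count_presence_changes
from .simulate import (
    TREND_ARCHETYPES,
    SimulationConfig,
    _draw_concordance_pair,
    evaluate_recovery,
    generate_study,
)
from .trends import assign_tendencies, fuzzy_cmeans

__all__ = [
    "null_calibration",
    "dap_recovery_benchmark",
    "six_type_grid_agreement",
    "six_type_mixture_recovery",
    "fcm_benchmark",
    "hypergeom_vs_enumeration",
    "presence_fixture",
    "presence_fixture_counts",
    "batch_adjust_benchmark",
]


def _two_group_design(n: int = 3) -> StudyDesign:
    rows = [
        {"sample_id": f"LD_{s}_r{i}", "region": "LD", "stage": s, "replicate": i}
        for s in ("A", "B")
        for i in range(1, n + 1)
    ]
    return StudyDesign(pd.DataFrame(rows), stages=("A", "B"), regions=("LD",))


def null_calibration(
    seed: int, n_features: int = 20_000, n: int = 3, sigma: float = 0.3
) -> dict[str, float]:
    """Fraction of raw p < 0.05 and BH q < 0.05 under the null.

    All features are drawn from one log-normal (equal group distributions),
    tested with the student variant at the study replication level.
    """
    rng = np.random.default_rng(seed)
    d = _two_group_design(n)
    values = 2.0 ** rng.normal(8.0, 1.0, size=(n_features, 1)) * 2.0 ** rng.normal(
        0.0, sigma, size=(n_features, 2 * n)
    )
    m = ExpressionMatrix(
        pd.DataFrame(values, index=[f"F{i}" for i in range(n_features)],
                     columns=d.sample_ids),
        "transcript", "linear",
    )
    c = ContrastSpec("stage_pair_within_region", ("LD", "A"), ("LD", "B"))
    recs = call_contrast(m, d, c, POLICIES["stage_dap"], variant="student")
    p = np.array([r.p_value for r in recs])
    q = np.array([r.q_value for r in recs])
    return {
        "raw_p_lt_05_fraction": float((p < 0.05).mean()),
        "bh_q_lt_05_fraction": float((q < 0.05).mean()),
        "n": len(recs),
    }


def dap_recovery_benchmark(
    seed: int, n_genes: int = 2000, effect: float = 1.5, sigma: float = 0.3,
    prevalence: float = 0.4,
) -> dict[str, float]:
    """Sensitivity and observed FDR of region-DAP calling on planted effects."""
    cfg = SimulationConfig(
        n_genes=n_genes,
        seed=seed,
        dap_fraction=prevalence,
        dap_log2_effect=effect,
        noise_sd_log2=sigma,
        presence_fraction=0.0,
        trend_fraction=0.0,
        concordance_fraction=0.0,
        detection_limit=0.0,
    )
    study = generate_study(cfg)
    c = ContrastSpec("region_within_stage", ("LD", "P28"), ("SD", "P28"))
    recs = call_contrast(study.protein, study.design, c, POLICIES["region_dap"])
    rep = evaluate_recovery(study.truth, dap_records=recs)
    return {
        "sensitivity": rep.dap_sensitivity,
        "observed_fdr": rep.dap_observed_fdr,
        "n": n_genes,
    }


def _predicate_oracle(rna: float, prot: float, t: float = 1.0) -> int:
    R, P = abs(rna) >= t, abs(prot) >= t
    S = (math.copysign(1, rna) == math.copysign(1, prot)) or rna == 0 or prot == 0
    if not R and not P:
        return 1
    if R and P:
        return 6 if S else 5
    if S:
        return 4
    return 2 if P else 3


def six_type_grid_agreement(step: float = 0.1, lim: float = 4.0) -> dict[str, float]:
    """Exhaustive grid check of the classifier against predicate evaluation."""
    vals = np.round(np.arange(-lim, lim + step / 2, step), 10)
    R, P = np.meshgrid(vals, vals, indexing="ij")
    out = classify_six_types_array(R.ravel(), P.ravel())
    oracle = np.array([_predicate_oracle(r, p) for r, p in zip(R.ravel(), P.ravel())])
    total = (out >= 1).all() and (out <= 6).all()
    return {
        "agreement_fraction": float((out == oracle).mean()) if total else 0.0,
        "n": int(out.size),
    }


def six_type_mixture_recovery(seed: int, n: int = 10_000) -> dict[str, float]:
    """Max absolute error (percentage points) of recovered type proportions.

    Types are drawn from the default planted mixture; fold-change pairs are
    generated in each type's interior region and classified back.
    """
    cfg = SimulationConfig()
    rng = np.random.default_rng(seed)
    mixture = np.asarray(cfg.concordance_mixture)
    planted = rng.choice(np.arange(1, 7), size=n, p=mixture)
    pairs = np.array(
        [
            _draw_concordance_pair(
                int(ct), rng, cfg.concordance_threshold_log2,
                cfg.concordance_margin_log2, cfg.concordance_max_log2,
            )
            for ct in planted
        ]
    )
    assigned = classify_six_types_array(pairs[:, 0], pairs[:, 1])
    recovered = np.array([(assigned == k).mean() for k in range(1, 7)])
    return {
        "max_abs_error_pct": float(np.abs(recovered - mixture).max() * 100),
        "accuracy": float((assigned == planted).mean()),
        "n": n,
    }


def fcm_benchmark(
    seed: int, n_recovery_seeds: int = 10, n_monotone_seeds: int = 50,
    sigma: float = 0.3,
) -> dict[str, float]:
    """Objective monotonicity, archetype recovery and membership validity."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([1, 2, 3, 4], 100)
    X = np.array([TREND_ARCHETYPES[l] for l in labels]) + rng.normal(
        0, sigma, (400, 6)
    )
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    min_ari = 1.0
    max_rowsum_err = 0.0
    for s in range(n_recovery_seeds):
        model = fuzzy_cmeans(X, c=4, m=2.0, seed=s)
        asg = assign_tendencies(model, feature_ids=[str(i) for i in range(400)])
        ari = adjusted_rand_score(labels, [a.tendency for a in asg])
        min_ari = min(min_ari, ari)
        max_rowsum_err = max(
            max_rowsum_err, float(np.abs(model.membership.sum(1) - 1).max())
        )
    Y = rng.normal(size=(100, 6))
    n_violations = 0
    for s in range(n_monotone_seeds):
        model = fuzzy_cmeans(Y, c=4, m=2.0, seed=s)
        if (np.diff(model.objective_history) > 1e-9).any():
            n_violations += 1
    return {
        "min_recovery_ari": float(min_ari),
        "max_membership_rowsum_error": max_rowsum_err,
        "monotonicity_violations": n_violations,
        "n": 400,
    }


def _enumeration_tail(k: int, K: int, n: int, N: int) -> float:
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if 0 <= n - j <= N - K:
            acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def hypergeom_vs_enumeration(max_N: int = 25) -> dict[str, float]:
    """Max |error| of the hypergeometric tail vs exact enumeration, N <= max_N."""
    worst = 0.0
    count = 0
    for N in range(max_N + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    exact = _enumeration_tail(k, K, n, N)
                    got = hypergeom_upper_tail(k, K, n, N)
                    worst = max(worst, abs(got - exact))
                    count += 1
    return {"max_abs_error": worst, "n": count}


def presence_fixture() -> tuple[ExpressionMatrix, StudyDesign]:
    """A 20-feature hand-built fixture over 3 stages x 2 regions x 3 reps.

    Feature groups (5 each): clean gains at S1->S2 in LD, clean losses at
    S2->S3 in SD, always-detected, and mixed/partial patterns that must not
    be called under the strict policy.
    """
    stages = ("S1", "S2", "S3")
    rows_meta = [
        {"sample_id": f"{r}_{s}_r{i}", "region": r, "stage": s, "replicate": i}
        for r in ("LD", "SD")
        for s in stages
        for i in (1, 2, 3)
    ]
    d = StudyDesign(pd.DataFrame(rows_meta), stages=stages)
    data = {}
    # LD columns: S1 r1-3, S2 r1-3, S3 r1-3; then SD likewise
    for i in range(5):  # gain at S1->S2 in LD, constant in SD
        data[f"gain{i}"] = [0, 0, 0, 5, 6, 7, 5, 6, 7] + [3] * 9
    for i in range(5):  # loss at S2->S3 in SD, constant in LD
        data[f"loss{i}"] = [3] * 9 + [5, 6, 7, 5, 6, 7, 0, 0, 0]
    for i in range(5):  # always detected
        data[f"flat{i}"] = [2] * 18
    # mixed patterns: partial detection blocks strict calls
    data["part0"] = [1, 0, 0, 5, 6, 7, 5, 6, 7] + [3] * 9  # detected once before
    data["part1"] = [0, 0, 0, 5, 0, 0, 5, 5, 5] + [3] * 9  # partial at S2
    data["part2"] = [3] * 9 + [5, 6, 7, 1, 0, 0, 0, 0, 0]  # partial loss S2->S3
    data["part3"] = [0] * 18  # never detected
    data["part4"] = [0, 0, 0, 0, 0, 0, 5, 6, 7] + [3] * 9  # gain at S2->S3 in LD
    m = ExpressionMatrix(
        pd.DataFrame.from_dict(data, orient="index",
                               columns=[r["sample_id"] for r in rows_meta]).astype(float),
        "protein", "linear",
    )
    return m, d


def presence_fixture_counts(policy: str = "all_replicates") -> pd.DataFrame:
    m, d = presence_fixture()
    return count_presence_changes(m, d, policy=policy)


def batch_adjust_benchmark(n_features: int = 20) -> dict[str, float]:
    """Noiseless two-batch shift with a protected covariate contrast.

    Returns the worst residual batch-mean gap and the worst deviation of
    the covariate contrast from its planted value (both should be ~0).
    """
    rng = np.random.default_rng(12345)
    base = rng.normal(5, 1, n_features)
    cols, batch, group = {}, {}, {}
    for b, (label, shift) in enumerate([("A", 0.0), ("B", 3.0)]):
        for i in range(6):
            s = f"{label}{i}"
            g = i % 2  # covariate group, balanced within batch
            cols[s] = base + shift + 2.0 * g
            batch[s] = label
            group[s] = f"g{g}"
    x = pd.DataFrame(cols, index=[f"F{i}" for i in range(n_features)])
    covariates = pd.DataFrame({"group": pd.Series(group)})
    out = batch_adjust(x, pd.Series(batch), covariates=covariates)
    bseries = pd.Series(batch)
    gap = (
        out.loc[:, bseries == "A"].mean(axis=1) - out.loc[:, bseries == "B"].mean(axis=1)
    )
    gseries = pd.Series(group)
    contrast = (
        out.loc[:, gseries == "g1"].mean(axis=1) - out.loc[:, gseries == "g0"].mean(axis=1)
    )
    return {
        "max_batch_mean_gap": float(np.abs(gap).max()),
        "max_covariate_error": float(np.abs(contrast - 2.0).max()),
        "n": n_features,
    }
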