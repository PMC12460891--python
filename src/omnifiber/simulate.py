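"""Synthetic paired protein/RNA study generator with machine-readable truth.

Emulates the 2-region x 6-stage x 3-replicate design: per-gene baseline
log2 abundances, planted effect classes, log-normal replicate noise, and
mechanistic protein non-detection (linear values below a detection limit
are stored as 0, mirroring the LFQ "not detected" convention). Planted
classes, each recorded in the truth tables:

- **dap**: a region shift (log2 effect, random sign) on the protein level
  at every stage — recoverable by region differential calling.
- **presence**: a gain or loss event at one adjacent-stage transition in
  one region — abundance sits far below the detection limit on the absent
  side and far above on the present side, so presence truth is exact.
- **trend**: one of four temporal archetypes added to both regions
  (decline from E90, birth peak, birth trough, monotone rise).
- **concordance**: paired RNA/protein region effects drawn from the
  interior of one of the six concordance-type regions (margin 0.25 log2
  units from every boundary) so planted types survive noise.

Annotation terms are drawn over the gene universe; a few terms are
constructed to be over-represented in the planted differential genes.
One global seed drives a spawned per-section seed sequence, so the same
config + seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .matrix import DEFAULT_REGIONS, DEFAULT_STAGES, ExpressionMatrix, StudyDesign

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "SimulatedStudy",
    "generate_study",
    "evaluate_recovery",
    "RecoveryReport",
    "TREND_ARCHETYPES",
]

#: Standardized-shape archetypes over the six stages (before amplitude
#: scaling): decline from E90 onward, peak around birth, trough around
#: birth, monotone rise.
TREND_ARCHETYPES: dict[int, np.ndarray] = {
    1: np.array([0.8, 0.9, 1.0, -0.1, -0.9, -1.3]),
    2: np.array([-1.0, -0.3, 0.5, 1.2, 0.4, -0.9]),
    3: np.array([0.9, 0.3, -0.5, -1.2, -0.3, 0.9]),
    4: np.array([-1.2, -0.8, -0.2, 0.2, 0.8, 1.2]),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generator parameters; defaults are the benchmark conditions."""

    n_genes: int = 2000
    regions: tuple[str, ...] = DEFAULT_REGIONS
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates: int = 3
    # abundance model
    protein_baseline_mean_log2: float = 20.0
    protein_baseline_sd_log2: float = 1.5
    rna_baseline_mean_log2: float = 6.0
    rna_baseline_sd_log2: float = 1.5
    noise_sd_log2: float = 0.3
    detection_limit: float = 2.0**14  # linear LFQ; protein values below -> 0
    # planted classes
    dap_fraction: float = 0.05
    dap_log2_effect: float = 1.5
    presence_fraction: float = 0.02
    presence_margin_log2: float = 5.0  # distance of means from the detection limit
    trend_fraction: float = 0.3
    trend_amplitude_log2: float = 1.5
    concordance_fraction: float = 0.1
    concordance_mixture: tuple[float, ...] = (0.60, 0.15, 0.15, 0.04, 0.03, 0.03)
    concordance_threshold_log2: float = 1.0
    concordance_margin_log2: float = 0.25
    concordance_max_log2: float = 3.0
    # annotation structure
    n_terms: int = 30
    term_size_range: tuple[int, int] = (10, 50)
    n_enriched_terms: int = 3
    enriched_overlap: float = 0.6  # fraction of an enriched term drawn from DAP genes
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.dap_fraction,
            self.presence_fraction,
            self.trend_fraction,
            self.concordance_fraction,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("planted fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("planted fractions sum above 1; infeasible partition")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if abs(sum(self.concordance_mixture) - 1) > 1e-9 or len(self.concordance_mixture) != 6:
            raise ValueError("concordance_mixture must be 6 fractions summing to 1")
        if self.concordance_margin_log2 >= self.concordance_threshold_log2:
            raise ValueError("concordance margin must be below the threshold")


@dataclass
class TruthTables:
    """Planted per-gene truth plus term-level enrichment flags."""

    genes: pd.DataFrame  # gene_id, role, effect columns
    terms: pd.DataFrame  # term_id, n_members, enriched

    @property
    def planted_dap_ids(self) -> set[str]:
        g = self.genes
        return set(g.loc[g["prot_region_lfc"] != 0, "gene_id"])

    @property
    def enriched_term_ids(self) -> set[str]:
        return set(self.terms.loc[self.terms["enriched"], "term_id"])


@dataclass
class SimulatedStudy:
    protein: ExpressionMatrix
    rna: ExpressionMatrix
    design: StudyDesign
    annotations: dict[str, set[str]]
    truth: TruthTables
    config: SimulationConfig = field(repr=False, default=None)


def _draw_concordance_pair(
    ctype: int, rng: np.random.Generator, t: float, margin: float, cap: float
) -> tuple[float, float]:
    """A (rna, prot) log2 effect pair in the interior of one type's region."""
    lo_b, hi_b = margin, t - margin  # "unchanged" magnitude band (nonzero)
    lo_a, hi_a = t + margin, cap  # "changed" magnitude band
    sign = rng.choice([-1.0, 1.0])
    below = lambda: rng.uniform(lo_b, hi_b)
    above = lambda: rng.uniform(lo_a, hi_a)
    if ctype == 1:
        return rng.choice([-1.0, 1.0]) * below(), rng.choice([-1.0, 1.0]) * below()
    if ctype == 6:
        return sign * above(), sign * above()
    if ctype == 5:
        return sign * above(), -sign * above()
    if ctype == 4:
        if rng.random() < 0.5:
            return sign * above(), sign * below()
        return sign * below(), sign * above()
    if ctype == 2:
        return -sign * below(), sign * above()
    if ctype == 3:
        return sign * above(), -sign * below()
    raise ValueError(f"unknown concordance type {ctype}")


def generate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate (protein, rna, design, annotations, truth) for one config."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.spawn(6)
    rng_roles = np.random.default_rng(seeds[0])
    rng_base = np.random.default_rng(seeds[1])
    rng_effects = np.random.default_rng(seeds[2])
    rng_noise = np.random.default_rng(seeds[3])
    rng_ann = np.random.default_rng(seeds[4])

    G = cfg.n_genes
    n_stages = len(cfg.stages)
    gene_ids = [f"G{i:05d}" for i in range(G)]

    # --- role partition ---------------------------------------------------
    n_dap = int(round(cfg.dap_fraction * G))
    n_presence = int(round(cfg.presence_fraction * G))
    n_trend = int(round(cfg.trend_fraction * G))
    n_conc = int(round(cfg.concordance_fraction * G))
    perm = rng_roles.permutation(G)
    cursor = 0
    idx_dap = perm[cursor : cursor + n_dap]; cursor += n_dap
    idx_presence = perm[cursor : cursor + n_presence]; cursor += n_presence
    idx_trend = perm[cursor : cursor + n_trend]; cursor += n_trend
    idx_conc = perm[cursor : cursor + n_conc]; cursor += n_conc
    roles = np.full(G, "null", dtype=object)
    roles[idx_dap] = "dap"
    roles[idx_presence] = "presence"
    roles[idx_trend] = "trend"
    roles[idx_conc] = "concordance"

    # --- baseline means ---------------------------------------------------
    base_p = rng_base.normal(cfg.protein_baseline_mean_log2, cfg.protein_baseline_sd_log2, G)
    base_r = rng_base.normal(cfg.rna_baseline_mean_log2, cfg.rna_baseline_sd_log2, G)

    # per-gene x region x stage log2 means
    Mp = np.broadcast_to(base_p[:, None, None], (G, 2, n_stages)).copy()
    Mr = np.broadcast_to(base_r[:, None, None], (G, 2, n_stages)).copy()

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": roles,
            "prot_region_lfc": 0.0,
            "rna_region_lfc": 0.0,
            "trend_archetype": 0,
            "concordance_type": 0,
            "presence_direction": "",
            "presence_region": "",
            "presence_from": "",
            "presence_to": "",
        }
    )

    # DAP: protein region shift (region 0 vs region 1), random sign
    signs = rng_effects.choice([-1.0, 1.0], size=n_dap)
    for g, s in zip(idx_dap, signs):
        eff = s * cfg.dap_log2_effect
        Mp[g, 0, :] += eff
        truth.loc[g, "prot_region_lfc"] = eff

    # presence: gain/loss at one transition in one region
    dl_log2 = np.log2(cfg.detection_limit) if cfg.detection_limit > 0 else 0.0
    low = dl_log2 - cfg.presence_margin_log2
    high = dl_log2 + cfg.presence_margin_log2
    for g in idx_presence:
        direction = rng_effects.choice(["increasing", "decreasing"])
        tr = int(rng_effects.integers(n_stages - 1))
        region_i = int(rng_effects.integers(2))
        if direction == "increasing":
            Mp[g, region_i, : tr + 1] = low
            Mp[g, region_i, tr + 1 :] = high
        else:
            Mp[g, region_i, : tr + 1] = high
            Mp[g, region_i, tr + 1 :] = low
        # the other region stays safely detected
        Mp[g, 1 - region_i, :] = high
        truth.loc[g, "presence_direction"] = direction
        truth.loc[g, "presence_region"] = cfg.regions[region_i]
        truth.loc[g, "presence_from"] = cfg.stages[tr]
        truth.loc[g, "presence_to"] = cfg.stages[tr + 1]

    # trend: archetype added to both regions (protein and RNA)
    archetypes = rng_effects.integers(1, 5, size=n_trend)
    for g, a in zip(idx_trend, archetypes):
        shape = TREND_ARCHETYPES[int(a)] * cfg.trend_amplitude_log2
        Mp[g, :, :] += shape[None, :]
        Mr[g, :, :] += shape[None, :]
        truth.loc[g, "trend_archetype"] = int(a)

    # concordance: paired region effects in a type's interior
    ctypes = rng_effects.choice(
        np.arange(1, 7), size=n_conc, p=np.asarray(cfg.concordance_mixture)
    )
    for g, ct in zip(idx_conc, ctypes):
        rna_lfc, prot_lfc = _draw_concordance_pair(
            int(ct),
            rng_effects,
            cfg.concordance_threshold_log2,
            cfg.concordance_margin_log2,
            cfg.concordance_max_log2,
        )
        Mr[g, 0, :] += rna_lfc
        Mp[g, 0, :] += prot_lfc
        truth.loc[g, "concordance_type"] = int(ct)
        truth.loc[g, "rna_region_lfc"] = rna_lfc
        truth.loc[g, "prot_region_lfc"] = prot_lfc

    # --- sample generation -------------------------------------------------
    sample_ids, meta_rows = [], []
    for ri, region in enumerate(cfg.regions):
        for si, stage in enumerate(cfg.stages):
            for rep in range(1, cfg.replicates + 1):
                sample_ids.append(f"{region}_{stage}_r{rep}")
                meta_rows.append(
                    {"sample_id": sample_ids[-1], "region": region, "stage": stage,
                     "replicate": rep}
                )
    design = StudyDesign(pd.DataFrame(meta_rows), stages=cfg.stages, regions=cfg.regions)

    n_samples = len(sample_ids)
    prot = np.empty((G, n_samples))
    rna = np.empty((G, n_samples))
    col = 0
    for ri in range(len(cfg.regions)):
        for si in range(n_stages):
            for _ in range(cfg.replicates):
                noise_p = rng_noise.normal(0.0, cfg.noise_sd_log2, G)
                noise_r = rng_noise.normal(0.0, cfg.noise_sd_log2, G)
                prot[:, col] = 2.0 ** (Mp[:, ri, si] + noise_p)
                rna[:, col] = 2.0 ** (Mr[:, ri, si] + noise_r)
                col += 1
    prot[prot < cfg.detection_limit] = 0.0  # mechanistic non-detection

    protein_m = ExpressionMatrix(
        pd.DataFrame(prot, index=gene_ids, columns=sample_ids), "protein", "linear"
    )
    rna_m = ExpressionMatrix(
        pd.DataFrame(rna, index=gene_ids, columns=sample_ids), "transcript", "linear"
    )

    # --- annotation terms ---------------------------------------------------
    ann: dict[str, set[str]] = {}
    term_rows = []
    dap_pool = [gene_ids[g] for g in idx_dap]
    lo, hi = cfg.term_size_range
    n_enriched = min(cfg.n_enriched_terms, cfg.n_terms) if dap_pool else 0
    for ti in range(cfg.n_terms):
        term_id = f"TERM{ti:03d}"
        size = int(rng_ann.integers(lo, hi + 1))
        enriched = ti < n_enriched
        if enriched:
            n_from_dap = min(int(round(cfg.enriched_overlap * size)), len(dap_pool))
            members = set(rng_ann.choice(dap_pool, size=n_from_dap, replace=False))
            others = [g for g in gene_ids if g not in members]
            members |= set(rng_ann.choice(others, size=size - n_from_dap, replace=False))
        else:
            members = set(rng_ann.choice(gene_ids, size=size, replace=False))
        ann[term_id] = members
        term_rows.append({"term_id": term_id, "n_members": len(members), "enriched": enriched})

    truth_tables = TruthTables(genes=truth, terms=pd.DataFrame(term_rows))
    return SimulatedStudy(protein_m, rna_m, design, ann, truth_tables, cfg)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    dap_sensitivity: float | None = None
    dap_observed_fdr: float | None = None
    trend_agreement: float | None = None
    concordance_confusion: pd.DataFrame | None = None
    concordance_accuracy: float | None = None
    enrichment_hit_rate: float | None = None


def evaluate_recovery(
    truth: TruthTables,
    dap_records=None,
    trend_assignments=None,
    concordance_records=None,
    enrichment_results=None,
) -> RecoveryReport:
    """Score pipeline outputs against the planted truth.

    All inputs are optional; each provided output fills the corresponding
    report field. Raises if an output refers to features outside the
    simulated gene universe.
    """
    universe = set(truth.genes["gene_id"])
    report = RecoveryReport()

    if dap_records is not None:
        called = {r.feature_id for r in dap_records if r.called}
        tested = {r.feature_id for r in dap_records}
        if not tested <= universe:
            raise ValueError("differential records refer to unknown features")
        planted = truth.planted_dap_ids
        if planted:
            report.dap_sensitivity = len(called & planted) / len(planted)
        report.dap_observed_fdr = (
            len(called - planted) / len(called) if called else 0.0
        )

    if trend_assignments is not None:
        planted_trend = truth.genes.set_index("gene_id")["trend_archetype"]
        ids = [a.feature_id for a in trend_assignments]
        if not set(ids) <= universe:
            raise ValueError("trend assignments refer to unknown features")
        mask = [planted_trend.get(i, 0) > 0 for i in ids]
        true_labels = [int(planted_trend[i]) for i, m in zip(ids, mask) if m]
        pred_labels = [a.tendency for a, m in zip(trend_assignments, mask) if m]
        if true_labels:
            report.trend_agreement = float(adjusted_rand_score(true_labels, pred_labels))

    if concordance_records is not None:
        planted_type = truth.genes.set_index("gene_id")["concordance_type"]
        rows = [
            (int(planted_type[r.gene_id]), r.type)
            for r in concordance_records
            if planted_type.get(r.gene_id, 0) > 0
        ]
        if rows:
            df = pd.DataFrame(rows, columns=["planted", "assigned"])
            report.concordance_confusion = pd.crosstab(df["planted"], df["assigned"])
            report.concordance_accuracy = float((df["planted"] == df["assigned"]).mean())

    if enrichment_results is not None:
        enriched = truth.enriched_term_ids
        if enriched:
            top = {r.term_id for r in enrichment_results[: len(enriched)]}
            report.enrichment_hit_rate = len(top & enriched) / len(enriched)

    return report
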