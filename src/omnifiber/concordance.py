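"""Six-type RNA-protein fold-change concordance classification.

Paired log2 fold changes (RNA vs protein, computed identically from linear
group means with a pseudocount) place each gene in one of six categories.
With threshold t on |log2FC| (default 1, i.e. |FC| = 2) and predicates
R = |rna| >= t, P = |prot| >= t, S = sign agreement:

=====  =======================================================
Type   definition (precedence_v1 rule, evaluated top to bottom)
=====  =======================================================
1      neither changed (not R and not P)
6      both changed, same direction (R and P and S)
5      both changed, opposite direction (R and P and not S)
4      exactly one changed, directions agree
2      only protein changed, directions disagree
3      only RNA changed, directions disagree
=====  =======================================================

The published category definitions overlap (a "changed at either level"
reading of Type 4 intersects Types 2/3/6); precedence_v1 is the documented
disambiguation, with both-changed cases taking priority and sign agreement
splitting the one-changed cases. A zero fold change agrees in sign with
either direction. The rule name is stamped into every record so alternative
readings can be added side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import ContrastSpec
from .matrix import ExpressionMatrix, StudyDesign

__all__ = [
    "ConcordanceRecord",
    "classify_six_types",
    "classify_six_types_array",
    "paired_fold_changes",
    "classify_records",
    "type_proportions",
]

RULE_VARIANTS = ("precedence_v1",)


@dataclass
class ConcordanceRecord:
    gene_id: str
    stage_or_contrast: str
    rna_log2fc: float
    prot_log2fc: float
    type: int  # 1..6
    rule_variant: str = "precedence_v1"


def classify_six_types_array(
    rna_log2fc: np.ndarray,
    prot_log2fc: np.ndarray,
    t: float = 1.0,
    rule_variant: str = "precedence_v1",
) -> np.ndarray:
    """Vectorized six-type classification; see module docstring for the rule."""
    if rule_variant not in RULE_VARIANTS:
        raise ValueError(f"unknown rule variant {rule_variant!r}")
    if t <= 0:
        raise ValueError("threshold t must be > 0")
    r = np.asarray(rna_log2fc, dtype=float)
    p = np.asarray(prot_log2fc, dtype=float)
    if not (np.isfinite(r).all() and np.isfinite(p).all()):
        raise ValueError("non-finite fold changes")
    R = np.abs(r) >= t
    P = np.abs(p) >= t
    S = (np.sign(r) == np.sign(p)) | (r == 0) | (p == 0)
    out = np.zeros(r.shape, dtype=int)
    out[~R & ~P] = 1
    out[R & P & S] = 6
    out[R & P & ~S] = 5
    one = R ^ P
    out[one & S] = 4
    out[one & ~S & P] = 2
    out[one & ~S & R] = 3
    return out


def classify_six_types(
    rna_log2fc: float,
    prot_log2fc: float,
    t: float = 1.0,
    rule_variant: str = "precedence_v1",
) -> int:
    """Classify one (rna, prot) log2 fold-change pair into Types 1-6."""
    return int(
        classify_six_types_array(
            np.array([rna_log2fc]), np.array([prot_log2fc]), t, rule_variant
        )[0]
    )


def paired_fold_changes(
    rna: ExpressionMatrix,
    prot: ExpressionMatrix,
    d: StudyDesign,
    contrast: ContrastSpec,
    id_map: dict[str, str] | None = None,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Per-gene log2 fold changes computed identically in both modalities.

    ``id_map`` maps gene id (RNA row) to protein id (protein row); None
    means the two matrices share identifiers. Fold changes are
    log2((mean_a + pseudocount)/(mean_b + pseudocount)) on linear group
    means. Genes represented or detected in only one modality are excluded;
    the count of exclusions is returned alongside the table.
    """
    if rna.scale != "linear" or prot.scale != "linear":
        raise ValueError("paired_fold_changes expects linear-scale matrices")
    if id_map is not None and len(id_map) == 0:
        raise ValueError("empty gene-protein id mapping")
    d.validate_against(rna)
    d.validate_against(prot)
    from .differential import _resolve_group

    sa = _resolve_group(d, contrast.group_a)
    sb = _resolve_group(d, contrast.group_b)
    rna_a = [s for s in sa if s in rna.data.columns]
    rna_b = [s for s in sb if s in rna.data.columns]
    prot_a = [s for s in sa if s in prot.data.columns]
    prot_b = [s for s in sb if s in prot.data.columns]
    if not (rna_a and rna_b and prot_a and prot_b):
        raise ValueError(f"contrast {contrast.label} not resolvable in both modalities")

    if id_map is None:
        id_map = {g: g for g in rna.feature_ids}

    rows = []
    n_excluded = 0
    prot_index = set(prot.data.index)
    selected = rna.data[rna_a + rna_b]
    for gene, pid in id_map.items():
        if gene not in rna.data.index or pid not in prot_index:
            n_excluded += 1
            continue
        rvals = rna.data.loc[gene]
        pvals = prot.data.loc[pid]
        # require detection in at least one selected sample per modality
        if (rvals[rna_a + rna_b] == 0).all() or (pvals[prot_a + prot_b] == 0).all():
            n_excluded += 1
            continue
        r_fc = np.log2(
            (rvals[rna_a].mean() + pseudocount) / (rvals[rna_b].mean() + pseudocount)
        )
        p_fc = np.log2(
            (pvals[prot_a].mean() + pseudocount) / (pvals[prot_b].mean() + pseudocount)
        )
        rows.append(
            {"gene_id": gene, "rna_log2fc": float(r_fc), "prot_log2fc": float(p_fc)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "rna_log2fc", "prot_log2fc"]), n_excluded


def classify_records(
    pairs: pd.DataFrame,
    stage_or_contrast: str,
    t: float = 1.0,
    rule_variant: str = "precedence_v1",
) -> list[ConcordanceRecord]:
    """Attach Type 1-6 labels to a paired fold-change table."""
    types = classify_six_types_array(
        pairs["rna_log2fc"].to_numpy(), pairs["prot_log2fc"].to_numpy(), t, rule_variant
    )
    return [
        ConcordanceRecord(
            gene_id=row.gene_id,
            stage_or_contrast=stage_or_contrast,
            rna_log2fc=float(row.rna_log2fc),
            prot_log2fc=float(row.prot_log2fc),
            type=int(tp),
            rule_variant=rule_variant,
        )
        for row, tp in zip(pairs.itertuples(index=False), types)
    ]


def type_proportions(records: list[ConcordanceRecord]) -> pd.DataFrame:
    """Per-group type fractions (p1..p6, summing to 1) plus raw counts.

    Groups are the ``stage_or_contrast`` labels; empty groups cannot occur
    because groups are induced by the records themselves.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame(
        [{"group": r.stage_or_contrast, "type": r.type} for r in records]
    )
    rows = []
    for group, sub in df.groupby("group", sort=True):
        counts = sub["type"].value_counts()
        n = len(sub)
        row: dict = {"group": group, "n": n}
        for k in range(1, 7):
            c = int(counts.get(k, 0))
            row[f"n{k}"] = c
            row[f"p{k}"] = c / n
        rows.append(row)
    return pd.DataFrame(rows)
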