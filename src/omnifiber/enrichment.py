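"""Over-representation testing of feature sets against annotation maps.

Given a foreground set (e.g., the proteins in one tendency, the genes of
one concordance type, or a presence-gain set), a background (by default the
detected features of the relevant matrix), and a term -> members map (SMART
domains, GO terms, KEGG pathways), each term is tested with the
hypergeometric upper tail P(X >= k) and BH-corrected over the tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "enrich",
    "read_annotation_map",
    "read_gmt",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # hits in foreground
    K: int  # term size in background
    n: int  # foreground size
    N: int  # background size
    p_value: float
    q_value: float
    fold_enrichment: float
    term_name: str = ""


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the number of annotated features in the
    background, n the foreground size, k the annotated features observed in
    the foreground. Computed via the survival function (stable in log space
    internally).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column tab-separated (term_id, feature_id[, term_name]) -> map."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed annotation line: {line!r}")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT format: term, description, then member features, tab-separated."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            ann[parts[0]] = set(parts[2:])
    return ann


def enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    ann: Mapping[str, set[str]],
    min_term_size: int = 3,
    max_term_size: int = 500,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every term in the foreground.

    Term sizes are counted within the background (annotated features outside
    the background are ignored, with a log note); terms outside
    [min_term_size, max_term_size] are not tested. BH q-values are computed
    over the tested terms only. Results sort by (p, term_id).
    """
    fg = set(foreground)
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    stray = fg - bg
    if stray:
        raise ValueError(
            f"foreground not a subset of background; offenders: {sorted(stray)[:10]}"
        )
    N, n = len(bg), len(fg)
    n_outside = sum(len(members - bg) for members in ann.values())
    if n_outside:
        logger.info("enrich: %d annotated features outside the background ignored", n_outside)

    tested: list[tuple[str, int, int]] = []
    for term_id in sorted(ann):
        members = ann[term_id] & bg
        K = len(members)
        if K == 0 or not (min_term_size <= K <= max_term_size):
            continue
        k = len(members & fg)
        tested.append((term_id, k, K))
    if not tested:
        return []
    p = np.array([hypergeom_upper_tail(k, K, n, N) for _, k, K in tested])
    q = bh_adjust(p)
    results = [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=float(pv),
            q_value=float(qv),
            fold_enrichment=(k / n) / (K / N) if n else 0.0,
        )
        for (term_id, k, K), pv, qv in zip(tested, p, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p_value,
                "q": r.q_value,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in results
        ]
    )
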