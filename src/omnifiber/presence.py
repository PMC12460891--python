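"""Presence/absence dynamics between adjacent developmental stages.

A protein "increases" at a transition when it appears (LFQ intensity > 0)
at the later stage but was absent (LFQ = 0) at the earlier one, and
"decreases" under the mirror rule. Two strictness policies are offered:

- ``all_replicates`` (default): absence means every replicate is 0 and
  presence means every replicate is > 0 — the strict reading of the
  intensity rule.
- ``mean_based``: absence/presence judged on the stage mean (0 vs > 0).

For "decreasing" an additional ``delta`` mode is available in
:func:`find_decreasing` that flags any negative stage-mean change without
requiring absence, since the subtraction-based wording the rule derives
from is ambiguous; outputs are labeled with the policy used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, StudyDesign

__all__ = [
    "PresenceChange",
    "find_increasing",
    "find_decreasing",
    "count_presence_changes",
]

POLICIES = ("all_replicates", "mean_based")


@dataclass
class PresenceChange:
    feature_id: str
    region: str
    from_stage: str
    to_stage: str
    direction: str  # "increasing" | "decreasing"
    mean_delta: float  # linear LFQ units, mean(to) - mean(from)
    policy: str = "all_replicates"


def _check_transition(d: StudyDesign, transition: tuple[str, str]) -> None:
    from_stage, to_stage = transition
    adjacent = d.adjacent_transitions()
    if (from_stage, to_stage) not in adjacent:
        raise ValueError(
            f"({from_stage}, {to_stage}) is not an adjacent stage transition; "
            f"expected one of {adjacent}"
        )


def _stage_values(
    mp: ExpressionMatrix, d: StudyDesign, region: str, stage: str
) -> np.ndarray:
    samples = [s for s in d.samples_for(region=region, stage=stage) if s in mp.data.columns]
    if not samples:
        raise ValueError(f"no samples for region {region!r} stage {stage!r}")
    return mp.data[samples].to_numpy(dtype=float)


def _find_changes(
    mp: ExpressionMatrix,
    d: StudyDesign,
    region: str,
    transition: tuple[str, str],
    policy: str,
    direction: str,
) -> list[PresenceChange]:
    if mp.scale != "linear":
        raise ValueError("presence analysis expects a linear-scale protein matrix")
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    _check_transition(d, transition)
    from_stage, to_stage = transition
    F = _stage_values(mp, d, region, from_stage)
    T = _stage_values(mp, d, region, to_stage)
    if policy == "all_replicates":
        absent_from = (F == 0).all(axis=1)
        present_to = (T > 0).all(axis=1)
        absent_to = (T == 0).all(axis=1)
        present_from = (F > 0).all(axis=1)
    else:  # mean_based
        absent_from = F.mean(axis=1) == 0
        present_to = T.mean(axis=1) > 0
        absent_to = T.mean(axis=1) == 0
        present_from = F.mean(axis=1) > 0
    if direction == "increasing":
        hits = absent_from & present_to
    else:
        hits = present_from & absent_to
    delta = T.mean(axis=1) - F.mean(axis=1)
    out = []
    for i in np.flatnonzero(hits):
        out.append(
            PresenceChange(
                feature_id=mp.feature_ids[i],
                region=region,
                from_stage=from_stage,
                to_stage=to_stage,
                direction=direction,
                mean_delta=float(delta[i]),
                policy=policy,
            )
        )
    return out


def find_increasing(
    mp: ExpressionMatrix,
    d: StudyDesign,
    region: str,
    transition: tuple[str, str],
    policy: str = "all_replicates",
) -> list[PresenceChange]:
    """Proteins absent at ``from_stage`` and detected at ``to_stage``."""
    return _find_changes(mp, d, region, transition, policy, "increasing")


def find_decreasing(
    mp: ExpressionMatrix,
    d: StudyDesign,
    region: str,
    transition: tuple[str, str],
    policy: str = "all_replicates",
    delta_mode: bool = False,
) -> list[PresenceChange]:
    """Proteins detected at ``from_stage`` and absent at ``to_stage``.

    With ``delta_mode=True`` the absence requirement is dropped and any
    feature whose stage mean declines is reported instead (policy labeled
    ``"delta"``); this is the alternative reading of a subtraction-based
    decrease rule.
    """
    if delta_mode:
        _check_transition(d, transition)
        from_stage, to_stage = transition
        F = _stage_values(mp, d, region, from_stage)
        T = _stage_values(mp, d, region, to_stage)
        delta = T.mean(axis=1) - F.mean(axis=1)
        return [
            PresenceChange(
                feature_id=mp.feature_ids[i],
                region=region,
                from_stage=from_stage,
                to_stage=to_stage,
                direction="decreasing",
                mean_delta=float(delta[i]),
                policy="delta",
            )
            for i in np.flatnonzero(delta < 0)
        ]
    return _find_changes(mp, d, region, transition, policy, "decreasing")


def count_presence_changes(
    mp: ExpressionMatrix, d: StudyDesign, policy: str = "all_replicates"
) -> pd.DataFrame:
    """Counts of increasing/decreasing proteins per (region, transition).

    Rows are ordered by transition (chronological) then region then
    direction, matching how adjacent-stage gain/loss counts are tabulated.
    """
    rows = []
    for from_stage, to_stage in d.adjacent_transitions():
        for region in d.regions:
            inc = find_increasing(mp, d, region, (from_stage, to_stage), policy)
            dec = find_decreasing(mp, d, region, (from_stage, to_stage), policy)
            rows.append(
                {
                    "region": region,
                    "from_stage": from_stage,
                    "to_stage": to_stage,
                    "direction": "increasing",
                    "count": len(inc),
                }
            )
            rows.append(
                {
                    "region": region,
                    "from_stage": from_stage,
                    "to_stage": to_stage,
                    "direction": "decreasing",
                    "count": len(dec),
                }
            )
    return pd.DataFrame(rows)
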