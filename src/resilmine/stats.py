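"""Expert-validation statistics: inter-rater reliability, Likert retention,
consensus gating and between-group variance flagging.

A rating table is items x raters (ordinal 1-5 scores or categorical codes).
Panels of more than two raters are summarized by the mean of all pairwise
Cohen's kappa values.  Indicator retention follows the conjunctive Likert
rule (enough individual approvals AND a mean floor), consensus gating is a
simple approval-fraction threshold, and indicators whose mean scores differ
too much between rater strata (e.g. strict vs. voluntary intervention
jurisdictions) are flagged — but never dropped.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cohen_kappa",
    "panel_kappa",
    "likert_retention",
    "consensus_gate",
    "npi_variance_flag",
]

log = logging.getLogger(__name__)


def cohen_kappa(r1: Sequence, r2: Sequence) -> float:
    """kappa = (p_o - p_e) / (1 - p_e).

    Chance agreement p_e comes from the product of per-rater marginal
    category frequencies.  When both raters are constant and identical
    (p_e = 1) the value is defined as 1.0 by convention and logged.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-d sequences")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(np.dot(pa, pb))
    if p_e >= 1.0:
        log.info("cohen_kappa: both raters constant and equal; returning 1.0 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def panel_kappa(table: pd.DataFrame) -> float:
    """Mean pairwise Cohen's kappa over all rater columns (order-invariant)."""
    if table.shape[1] < 2:
        raise ValueError("panel requires at least 2 raters")
    pairs = list(combinations(table.columns, 2))
    return float(np.mean([cohen_kappa(table[c1], table[c2]) for c1, c2 in pairs]))


def likert_retention(
    table: pd.DataFrame,
    min_approvals: int = 4,
    approval_score: int = 4,
    mean_floor: float = 4.0,
    use_approvals: bool = True,
    use_mean: bool = True,
) -> list:
    """Retain an item iff enough raters score >= approval_score AND the item
    mean clears the floor (both sub-rules individually toggleable)."""
    retained = []
    for item, row in table.iterrows():
        scores = row.to_numpy(dtype=float)
        ok = True
        if use_approvals:
            ok &= int(np.sum(scores >= approval_score)) >= min_approvals
        if use_mean:
            ok &= float(scores.mean()) >= mean_floor
        if ok:
            retained.append(item)
    return retained


def consensus_gate(
    approval_fractions: Mapping[str, float], threshold: float = 2.0 / 3.0
) -> dict[str, bool]:
    """Pass iff the approval fraction is at least the threshold (so a
    reported 0.67 fails a 2/3 gate while an exact 2/3 passes)."""
    out = {}
    for item, frac in approval_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{item}: approval fraction {frac} outside [0, 1]")
        out[item] = frac >= threshold
    return out


def npi_variance_flag(
    group_means: Mapping[str, Sequence[float]],
    threshold: float = 0.20,
    metric: str = "relative_range",
) -> dict[str, bool]:
    """Flag items whose stratum means disperse by more than the threshold.

    ``relative_range``: (max - min) / overall mean;
    ``cv``: population coefficient of variation of the group means.
    Flagged items stay retained — the flag is advisory only.
    """
    flags = {}
    for item, means in group_means.items():
        m = np.asarray(means, dtype=float)
        if len(m) < 2:
            raise ValueError(f"{item}: need at least 2 group means")
        overall = float(m.mean())
        if overall == 0.0:
            raise ValueError(f"{item}: overall mean is zero")
        if metric == "relative_range":
            disp = float(m.max() - m.min()) / overall
        elif metric == "cv":
            disp = float(m.std()) / overall
        else:
            raise ValueError(f"unknown dispersion metric {metric!r}")
        flags[item] = disp > threshold
    return flags
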