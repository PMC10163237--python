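"""Cross-day classification of neurons over contingency reversals.

With the stimulus-reward contingency reversed between two sessions, a
neuron that keeps its Go (NoGo) preference must be tracking the expected
outcome: it is reward-selective (no-reward-selective).  A neuron whose
Go/NoGo preference flips has kept its preferred *stimulus* and is
mouse-selective.  Population-level inference uses a 3x3 contingency table
(day-1 x day-2 preference: Go / NoGo / none), a chi-square test of
independence, and Haberman adjusted residuals with planned comparisons on
the four preference-by-preference cells at p < 0.0125 (Bonferroni over the
four planned cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selectivity import GO_PREFERRING, NOGO_PREFERRING, NONE_LABEL
from .synthgen import RegistrationMap

REWARD_SELECTIVE = "reward-selective"
NO_REWARD_SELECTIVE = "no-reward-selective"
MOUSE_SELECTIVE = "mouse-selective"

PLANNED_ALPHA = 0.0125
_ORDER = (GO_PREFERRING, NOGO_PREFERRING, NONE_LABEL)
#: planned cells: maintained Go, maintained NoGo, reversed Go->NoGo, NoGo->Go
PLANNED_CELLS = ((0, 0), (1, 1), (0, 1), (1, 0))


@dataclass
class ContingencyResult:
    table: np.ndarray  # 3x3 counts, rows day 1, cols day 2, order Go/NoGo/none
    chi2: float
    p: float
    dof: int
    expected: np.ndarray
    adjusted_residuals: np.ndarray
    planned_p: dict[tuple[int, int], float]
    planned_significant: dict[tuple[int, int], bool]


@dataclass
class ReversalClassification:
    per_neuron: pd.DataFrame  # day1/day2 labels + class per linked neuron
    inference: ContingencyResult
    n_unlinked: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)


def _pair_class(l1: str, l2: str, reversed_pair: bool) -> str:
    if NONE_LABEL in (l1, l2):
        return NONE_LABEL
    if l1 == l2:
        return REWARD_SELECTIVE if l1 == GO_PREFERRING else NO_REWARD_SELECTIVE
    # preference flipped: stimulus-preserving under reversal
    return MOUSE_SELECTIVE if reversed_pair else NONE_LABEL


def contingency_table(labels_day1, labels_day2) -> np.ndarray:
    l1 = np.asarray(labels_day1)
    l2 = np.asarray(labels_day2)
    table = np.zeros((3, 3), dtype=float)
    for i, a in enumerate(_ORDER):
        for j, b in enumerate(_ORDER):
            table[i, j] = np.sum((l1 == a) & (l2 == b))
    return table


def contingency_inference(labels_day1, labels_day2) -> ContingencyResult:
    """Chi-square independence test + adjusted residuals on the 3x3 table.

    Zero margins are tolerated: cells in a zero row or column contribute
    nothing to the statistic, degrees of freedom shrink accordingly, and
    such planned cells are excluded (p = NaN).  Adjusted residual
    (Haberman): (O - E) / sqrt(E (1 - row_frac)(1 - col_frac)).
    """
    table = contingency_table(labels_day1, labels_day2)
    n = table.sum()
    if n == 0:
        raise ValueError("empty label sets")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (table - expected) ** 2 / expected
    live = expected > 0
    chi2 = float(np.nansum(np.where(live, contrib, 0.0)))
    dof = max((np.sum(row > 0) - 1) * (np.sum(col > 0) - 1), 0)
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    if (expected[live] < 5).any():
        warnings.warn("expected counts below 5; chi-square approximation is weak")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(expected * np.outer(1 - row / n, 1 - col / n))
        adj = (table - expected) / denom
    planned_p, planned_sig = {}, {}
    for cell in PLANNED_CELLS:
        if row[cell[0]] == 0 and col[cell[1]] == 0:
            planned_p[cell] = float("nan")
            planned_sig[cell] = False
            continue
        r = adj[cell]
        pv = float(2 * stats.norm.sf(abs(r))) if np.isfinite(r) else float("nan")
        planned_p[cell] = pv
        planned_sig[cell] = bool(np.isfinite(pv) and pv < PLANNED_ALPHA)
    return ContingencyResult(table, chi2, p, int(dof), expected, adj, planned_p, planned_sig)


def classify_across_reversal(
    labels_day1,
    labels_day2,
    regmap: RegistrationMap,
    reversed_pair: bool = True,
    day_i: int = 0,
    day_j: int = 1,
) -> ReversalClassification:
    """Assign each registered neuron a cross-day class and run the 3x3 test.

    ``labels_day1``/``labels_day2`` index into each day's own neuron order;
    the registration map supplies the one-to-one links.
    """
    l1 = np.asarray(labels_day1)
    l2 = np.asarray(labels_day2)
    idx1, idx2 = regmap.linked(day_i, day_j)
    n_unlinked = regmap.links.shape[0] - len(idx1)
    a, b = l1[idx1], l2[idx2]
    classes = [_pair_class(x, y, reversed_pair) for x, y in zip(a, b)]
    per_neuron = pd.DataFrame(
        {"idx_day1": idx1, "idx_day2": idx2, "label_day1": a, "label_day2": b,
         "class": classes}
    )
    counts = per_neuron["class"].value_counts().to_dict()
    return ReversalClassification(
        per_neuron, contingency_inference(a, b), n_unlinked, counts
    )


def stability_analysis(pref_day1, pref_day2, preference: str, opposite: str) -> dict:
    """Stable / reversed fractions of day-1 ``preference`` neurons vs chance.

    stable fraction: among day-1 neurons significantly preferring
    ``preference``, the fraction with the same significant preference on
    day 2; reversed fraction: the fraction with the ``opposite`` significant
    preference; chance: the overall day-2 fraction of ``preference``.
    Fractions are NaN when no day-1 neuron holds the preference.
    """
    p1 = np.asarray(pref_day1)
    p2 = np.asarray(pref_day2)
    sel = p1 == preference
    n_sel = int(sel.sum())
    chance = float(np.mean(p2 == preference)) if p2.size else float("nan")
    if n_sel == 0:
        return {"n_day1": 0, "stable_fraction": float("nan"),
                "reversed_fraction": float("nan"), "chance": chance}
    return {
        "n_day1": n_sel,
        "stable_fraction": float(np.mean(p2[sel] == preference)),
        "reversed_fraction": float(np.mean(p2[sel] == opposite)),
        "chance": chance,
    }
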