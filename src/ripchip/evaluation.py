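"""Ranking variables by how well they separate UP from LOW genes.

The separating power of a per-gene score is measured by the area under
the ROC curve, computed as the Mann-Whitney concordance: the fraction
of (UP, LOW) gene pairs in which the UP gene scores higher, ties
counting one half.  Higher score = UP is the positive orientation and
AUCs are reported as-is (not folded to >= 0.5).  Two paired AUCs are
compared with DeLong's test; score-level UP-vs-LOW comparisons use the
two-sample Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import CALL_LOW, CALL_UP


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    scores: np.ndarray
    labels: np.ndarray  # boolean, True = positive (UP)


def _as_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    out = np.empty(arr.shape, dtype=bool)
    for i, lab in enumerate(arr):
        if lab in (CALL_UP, 1, True):
            out[i] = True
        elif lab in (CALL_LOW, 0, False):
            out[i] = False
        else:
            raise ValueError(f"label {lab!r} is neither UP/1 nor LOW/0")
    return out


def roc_auc(scores: Sequence[float], labels) -> RocResult:
    """AUC via the rank-sum identity: U / (n_pos * n_neg), ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = _as_binary_labels(labels)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one gene in each class")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return RocResult(
        auc=float(u / (n_pos * n_neg)), n_pos=n_pos, n_neg=n_neg,
        scores=scores, labels=pos,
    )


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration for small tie-free samples (both n <= 25),
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(a.size, b.size) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# DeLong's test for two paired AUCs
# ---------------------------------------------------------------------------

def _delong_components(scores: np.ndarray, pos: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    x = scores[pos]
    y = scores[~pos]
    m, n = x.size, y.size
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - rx) / n
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    return auc, v10, v01


def delong_paired_test(scores_1, scores_2, labels) -> float:
    """Two-sided p-value for AUC(scores_1) == AUC(scores_2), both score
    vectors over the same labelled genes (paired DeLong test).

    Degenerate cases — identical score rankings or zero estimated
    variance of the difference — return p = 1.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    pos = _as_binary_labels(labels)
    if s1.shape != s2.shape or s1.shape != pos.shape:
        raise ValueError("score vectors and labels must have identical length")
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("need both classes")
    auc1, v10_1, v01_1 = _delong_components(s1, pos)
    auc2, v10_2, v01_2 = _delong_components(s2, pos)
    v10 = np.stack([v10_1, v10_2])
    v01 = np.stack([v01_1, v01_2])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc1 - auc2
    if var_diff <= 1e-16:
        return 1.0
    z = diff / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# ECDF
# ---------------------------------------------------------------------------

class ECDF:
    """Right-continuous empirical CDF: F(x) = (#values <= x) / n."""

    def __init__(self, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("ECDF needs at least one value")
        self.x = np.sort(values)
        self.n = values.size

    def __call__(self, x) -> np.ndarray | float:
        res = np.searchsorted(self.x, np.asarray(x, dtype=float), side="right") / self.n
        return float(res) if np.isscalar(x) else res

    def table(self) -> pd.DataFrame:
        """Step points (x, F(x)) for plotting/export."""
        xs, counts = np.unique(self.x, return_counts=True)
        return pd.DataFrame({"x": xs, "F": np.cumsum(counts) / self.n})


def ecdf(values: Sequence[float]) -> ECDF:
    return ECDF(values)


# ---------------------------------------------------------------------------
# per-variable ranking table
# ---------------------------------------------------------------------------

def variable_auc_table(variable_table, labels: pd.Series) -> pd.DataFrame:
    """AUC and rank-sum p for each variable, UP vs LOW genes.

    ``labels`` is a per-gene UP/LOW/NS series (e.g. SAM calls); NS genes
    are ignored.  Returns a DataFrame (variable, auc, p_value, n_up,
    n_low) sorted by descending AUC, mirroring the per-variable ranking
    panels of a RIP-Chip variable screen.
    """
    table = variable_table.table
    lab = labels.reindex(table.index)
    up = lab == CALL_UP
    low = lab == CALL_LOW
    keep = up | low
    if up.sum() == 0 or low.sum() == 0:
        raise ValueError("need both UP and LOW genes")
    rows = []
    for name in table.columns:
        scores = table.loc[keep, name].to_numpy(dtype=float)
        res = roc_auc(scores, up[keep].to_numpy())
        p = ranksum_test(table.loc[up, name], table.loc[low, name])
        rows.append({"variable": name, "auc": res.auc, "p_value": p,
                     "n_up": res.n_pos, "n_low": res.n_neg})
    return (
        pd.DataFrame(rows)
        .sort_values(["auc", "variable"], ascending=[False, True])
        .reset_index(drop=True)
    )
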