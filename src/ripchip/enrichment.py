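"""Enriched / underrepresented gene calls in IP vs FT samples.

The core is a SAM-style (Significance Analysis of Microarrays) relative
difference statistic with a permutation-based false discovery rate.
For gene g with IP-sample values a and FT-sample values b,

    d_g = (mean(a) - mean(b)) / (s_g + s0)

where s_g is the pooled standard error of the mean difference and s0 a
small positive "fudge" constant that damps the d-scores of low-variance
genes.  Class labels are permuted; for every observed |d| cutoff the FDR
is estimated as the median number of permutation calls divided by the
number of observed calls, and each gene receives as q-value the lowest
FDR at which it is called.  Genes at q <= threshold are labelled UP
(d > 0, enriched in IP) or LOW (d < 0, underrepresented).

Also here: exact hypergeometric and one-tailed Fisher tests for target
set overlaps, and the RT-qPCR fold-change normalisation (2^-ddCt over an
IP/Input RNA-percentage factor).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, ROLE_FT, ROLE_IP

logger = logging.getLogger(__name__)

CALL_UP = "UP"
CALL_LOW = "LOW"
CALL_NS = "NS"

DEFAULT_Q_THRESHOLD = 0.05  # q-value of 5%


@dataclass
class EnrichmentLabels:
    """Per-gene SAM output: d-score, q-value and UP/LOW/NS call."""

    table: pd.DataFrame  # columns: d, q, call; index: gene_id
    s0: float
    n_permutations: int
    q_threshold: float = DEFAULT_Q_THRESHOLD

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def genes(self, call: str) -> list[str]:
        return list(self.table.index[self.table["call"] == call])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path: str | Path, s0: float = float("nan"),
                 n_permutations: int = 0) -> "EnrichmentLabels":
        table = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(table=table, s0=s0, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# SAM statistic
# ---------------------------------------------------------------------------

def _pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled standard error of the mean difference, per gene (row).

    s = sqrt((1/na + 1/nb) * (SS_a + SS_b) / (na + nb - 2)); defined as 0
    when fewer than three values in total (no residual degrees of freedom).
    """
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    if df <= 0:
        return np.zeros(a.shape[0])
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / na + 1.0 / nb) * ss / df)


def sam_d_statistic(group_a: Sequence[float], group_b: Sequence[float], s0: float = 0.0) -> float:
    """SAM relative difference for one gene: (mean_a - mean_b) / (s + s0).

    With s0 = 0 this is the equal-variance two-sample t statistic.
    """
    a = np.asarray(group_a, dtype=float).reshape(1, -1)
    b = np.asarray(group_b, dtype=float).reshape(1, -1)
    if a.size == 0 and b.size == 0:
        raise ValueError("both groups are empty")
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one value")
    s = _pooled_se(a, b)[0]
    denom = s + s0
    if denom == 0:
        diff = a.mean() - b.mean()
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float((a.mean() - b.mean()) / denom)


def _d_vector(values: np.ndarray, is_a: np.ndarray, s0: float) -> np.ndarray:
    a = values[:, is_a]
    b = values[:, ~is_a]
    s = _pooled_se(a, b)
    diff = a.mean(axis=1) - b.mean(axis=1)
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
    # constant genes (zero spread and zero difference) are null, not NaN
    d[(denom == 0) & (diff == 0)] = 0.0
    return d


def median_s0(values: np.ndarray, is_a: np.ndarray) -> float:
    """Default fudge factor: median per-gene pooled SE (a fixed-percentile
    simplification of SAM's coefficient-of-variation minimising tuner)."""
    s = _pooled_se(values[:, is_a], values[:, ~is_a])
    return float(np.median(s))


def _label_permutations(n: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """Boolean masks assigning n_a of n columns to class A.

    All distinct assignments are enumerated when there are at most
    ``n_perm`` of them (logged); otherwise ``n_perm`` random assignments
    are drawn.
    """
    total = math.comb(n, n_a)
    if total <= n_perm:
        logger.info("using all %d distinct label permutations (requested %d)", total, n_perm)
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n_a)):
            masks[i, list(combo)] = True
        return masks
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n_a, replace=False)] = True
    return masks


def sam_enrichment(
    m: ExpressionMatrix,
    n_perm: int = 200,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    seed: int = 0,
    s0: float | None = None,
    paired: bool = False,
) -> EnrichmentLabels:
    """Call UP/LOW genes comparing IP against FT samples.

    Unpaired mode (default) permutes the IP/FT class assignment of the
    columns.  Paired mode pairs IP and FT columns by experiment index,
    computes a one-sample d on the paired differences, and permutes the
    signs of the pairs.  Identical inputs and seed give identical output.
    """
    sub = m.subset_roles([ROLE_IP, ROLE_FT])
    roles = np.array([s.role for s in sub.samples])
    if (roles == ROLE_IP).sum() < 2 or (roles == ROLE_FT).sum() < 2:
        raise ValueError("need at least two IP and two FT samples")
    values = sub.values.to_numpy(dtype=float)
    genes = sub.values.index
    rng = np.random.default_rng(seed)

    if paired:
        d, perm_d = _paired_d(sub, values, roles, s0, n_perm, rng)
        s0_used = float("nan") if s0 is None else s0
    else:
        is_ip = roles == ROLE_IP
        if s0 is None:
            s0 = median_s0(values, is_ip)
        d = _d_vector(values, is_ip, s0)
        masks = _label_permutations(len(roles), int(is_ip.sum()), n_perm, rng)
        perm_d = np.stack([_d_vector(values, mask, s0) for mask in masks])
        s0_used = s0

    q = _q_values(d, perm_d)
    call = np.where(
        (q <= q_threshold) & (d > 0), CALL_UP, np.where((q <= q_threshold) & (d < 0), CALL_LOW, CALL_NS)
    )
    table = pd.DataFrame({"d": d, "q": q, "call": call}, index=genes)
    return EnrichmentLabels(
        table=table, s0=s0_used, n_permutations=perm_d.shape[0], q_threshold=q_threshold
    )


def _paired_d(sub, values, roles, s0, n_perm, rng):
    ip_by_exp = {s.experiment: i for i, s in enumerate(sub.samples) if s.role == ROLE_IP}
    ft_by_exp = {s.experiment: i for i, s in enumerate(sub.samples) if s.role == ROLE_FT}
    exps = sorted(set(ip_by_exp) & set(ft_by_exp))
    if len(exps) < 2:
        raise ValueError("paired mode needs at least two complete IP/FT pairs")
    diffs = np.stack(
        [values[:, ip_by_exp[e]] - values[:, ft_by_exp[e]] for e in exps], axis=1
    )
    k = len(exps)

    def one_sample_d(x: np.ndarray, fudge: float) -> np.ndarray:
        se = x.std(axis=1, ddof=1) / math.sqrt(k)
        return x.mean(axis=1) / (se + fudge)

    if s0 is None:
        s0 = float(np.median(diffs.std(axis=1, ddof=1) / math.sqrt(k)))
    d = one_sample_d(diffs, s0)
    total = 2 ** k
    if total <= n_perm:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=k)))
        logger.info("using all %d sign flips (requested %d)", total, n_perm)
    else:
        signs = rng.choice([1.0, -1.0], size=(n_perm, k))
    perm_d = np.stack([one_sample_d(diffs * s[None, :], s0) for s in signs])
    return d, perm_d


def _q_values(d: np.ndarray, perm_d: np.ndarray) -> np.ndarray:
    """Permutation FDR: for each observed |d| cutoff, FDR = median false
    calls across permutations / observed calls (capped at 1); each gene's
    q is the minimum FDR over the cutoffs at which it is called."""
    absd = np.abs(d)
    order = np.argsort(-absd, kind="stable")  # descending |d|
    thresholds = absd[order]
    sorted_abs = np.sort(absd)  # ascending, for observed call counts
    n = len(d)
    observed = n - np.searchsorted(sorted_abs, thresholds, side="left")
    perm_abs_sorted = np.sort(np.abs(perm_d), axis=1)
    false = np.empty((perm_d.shape[0], n))
    for p in range(perm_d.shape[0]):
        false[p] = n - np.searchsorted(perm_abs_sorted[p], thresholds, side="left")
    median_false = np.median(false, axis=0)
    fdr = np.minimum(median_false / np.maximum(observed, 1), 1.0)
    # gene ranked k is called at its own cutoff and at every looser one
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# overlap tests
# ---------------------------------------------------------------------------

def _check_subsets(set_a: Collection, set_b: Collection, universe: Collection):
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    return a, b, universe


def hypergeometric_overlap(set_a: Collection, set_b: Collection, universe: Collection) -> float:
    """Upper-tail P[X >= |A∩B|] for the overlap of two gene sets drawn
    without replacement from ``universe`` (exact hypergeometric)."""
    a, b, universe = _check_subsets(set_a, set_b, universe)
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


def fisher_overlap_one_tail(set_a: Collection, set_b: Collection, universe: Collection) -> float:
    """One-tailed (enrichment) Fisher exact test on the 2x2 membership table."""
    a, b, universe = _check_subsets(set_a, set_b, universe)
    k = len(a & b)
    n = len(universe)
    table = [[k, len(a) - k], [len(b) - k, n - len(a) - len(b) + k]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def qpcr_fold_change(delta_delta_ct: float, pct_rna_ip: float, pct_rna_input: float) -> float:
    """2^-ddCt fold change divided by the IP/Input RNA-percentage factor.

    The normalisation factor is the percentage of extracted RNA assayed
    in the IP sample over the percentage assayed in the Input sample.
    """
    if pct_rna_ip <= 0 or pct_rna_input <= 0:
        raise ValueError("RNA percentages must be positive")
    factor = pct_rna_ip / pct_rna_input
    return float(2.0 ** (-delta_delta_ct) / factor)
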