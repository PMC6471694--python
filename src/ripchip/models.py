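"""Linear SVM models on single variables and variable pairs.

A linear soft-margin SVM is trained on one or two variables and scored
by leave-one-out cross-validation: each gene's decision value (signed
distance to the hyperplane) comes from a model trained on all other
genes, and the decision values are ranked by ROC-AUC against the UP/LOW
calls.  Because the F-variables span several orders of magnitude, each
feature is log10(x + eps) transformed (eps = smallest positive value /
10) and then z-scored on the training fold; both steps are configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .enrichment import CALL_LOW, CALL_UP
from .evaluation import _as_binary_labels, roc_auc
from .variables import VariableTable

DEFAULT_COST = 1.0


@dataclass
class SvmPairResult:
    variable_pair: tuple[str, str]
    loocv_auc: float
    decision_values: np.ndarray  # one per labelled gene
    labels: np.ndarray           # boolean, aligned with decision_values


def log_eps_transform(features: np.ndarray) -> np.ndarray:
    """log10(x + eps) per column; eps = smallest positive value / 10.

    Columns without positive values are left untouched.
    """
    out = features.astype(float).copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            continue
        out[:, j] = np.log10(col + positive.min() / 10.0)
    return out


def _fit_decision(x_train, y_train, x_test, cost: float) -> np.ndarray:
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LinearSVC(C=cost, loss="squared_hinge", dual=False, tol=1e-6, max_iter=20000)
    clf.fit((x_train - mu) / sd, y_train)
    return clf.decision_function((x_test - mu) / sd)


def loocv_decision_values(
    features: np.ndarray | pd.DataFrame,
    labels,
    cost: float = DEFAULT_COST,
    log_transform: bool = True,
) -> np.ndarray:
    """Leave-one-out decision values of a linear SVM.

    ``features`` is genes x k (k = 1 or 2); ``labels`` UP/LOW (or
    boolean).  For each gene the SVM is refit on all remaining genes and
    the held-out gene's signed distance to the hyperplane is recorded.
    Deterministic for fixed inputs.  Raises if any LOOCV training fold
    would lose a class (fewer than two genes in either class).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = _as_binary_labels(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on gene count")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least two genes for LOOCV")
    if log_transform:
        x = log_eps_transform(x)
    n = x.shape[0]
    decisions = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        decisions[i] = _fit_decision(x[mask], y[mask], x[i : i + 1], cost)[0]
        mask[i] = True
    return decisions


def loocv_auc(
    features, labels, cost: float = DEFAULT_COST, log_transform: bool = True
) -> SvmPairResult:
    """LOOCV decision values plus their ROC-AUC, for one feature set."""
    y = _as_binary_labels(labels)
    dec = loocv_decision_values(features, y, cost=cost, log_transform=log_transform)
    res = roc_auc(dec, y)
    names = tuple(features.columns) if isinstance(features, pd.DataFrame) else ("x0",)
    if len(names) == 1:
        names = (names[0], names[0])
    return SvmPairResult(variable_pair=names, loocv_auc=res.auc,
                         decision_values=dec, labels=y)


def pairwise_auc_matrix(
    v: VariableTable,
    labels: pd.Series,
    cost: float = DEFAULT_COST,
    variables: list[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """LOOCV AUC for every variable pair; the diagonal holds the
    single-variable model AUCs.

    ``labels`` is a per-gene UP/LOW/NS series; NS genes are excluded.
    The matrix is symmetric by construction (feature order is
    irrelevant to the SVM).  Pairs whose fit fails are reported as NaN
    rather than aborting the whole matrix.
    """
    names = list(variables) if variables is not None else list(v.table.columns)
    lab = labels.reindex(v.table.index)
    keep = lab.isin([CALL_UP, CALL_LOW])
    sub = v.table.loc[keep, names]
    y = (lab[keep] == CALL_UP).to_numpy()
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations_with_replacement(names, 2):
        cols = [a] if a == b else [a, b]
        try:
            dec = loocv_decision_values(
                sub[cols].to_numpy(), y, cost=cost, log_transform=log_transform
            )
            auc = roc_auc(dec, y).auc
        except ValueError:
            auc = np.nan
        out.loc[a, b] = auc
        out.loc[b, a] = auc
    return out
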