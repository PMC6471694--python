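"""miRNA-expression shuffling validation.

If a variable's power to separate UP from LOW genes really comes from
the miRNA expression profile, that power should collapse when the
profile is replaced by a simulated one.  Schemes:

``random_identity``
    the ordered top-k expression values are reassigned to k miRNAs
    drawn uniformly (without replacement) from all expressed miRNAs;
    miRNAs outside the draw get zero weight.  Tests whether the
    *identity* of the top-k miRNAs matters.
``within_top``
    the top-k values are permuted among the same k miRNAs.  Tests
    whether the specific value-to-miRNA assignment matters.
``within_top_fix_top_n`` / ``within_top_fix_low_n``
    the n highest (resp. lowest) of the top-k keep their values, the
    rest are permuted — sweeping n localises which miRNAs carry the
    signal.

Each simulation recomputes the variable and its ROC-AUC against fixed
UP/LOW labels; the exceedance fraction is the share of simulated AUCs
that reach the original AUC (ties count as reaching, so an identity
shuffle gives exactly 1.0; a strict ``>`` mode is available).  Total
expression mass over the shuffled subset is conserved exactly.  One
master seed spawns order-stable per-draw substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import CALL_LOW, CALL_UP
from .evaluation import roc_auc
from .expression import top_expressed
from .sequences import BindingSiteMatrix
from .variables import MIRNA_DEPENDENT, VARIABLE_NAMES

SCHEME_KINDS = (
    "random_identity",
    "within_top",
    "within_top_fix_top_n",
    "within_top_fix_low_n",
)


@dataclass(frozen=True)
class ShuffleScheme:
    kind: str
    k: int = 50
    n_fixed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.n_fixed < 0 or self.n_fixed > self.k:
            raise ValueError("need 0 <= n_fixed <= k")
        if self.kind in ("random_identity", "within_top") and self.n_fixed:
            raise ValueError(f"n_fixed does not apply to {self.kind}")


@dataclass
class ShuffleResult:
    original_auc: float
    simulated_aucs: np.ndarray
    exceedance_fraction: float
    scheme: ShuffleScheme
    seed: int
    variable: str
    mirna_dependent: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variable": self.variable,
            "scheme": {"kind": self.scheme.kind, "k": self.scheme.k,
                       "n_fixed": self.scheme.n_fixed},
            "seed": self.seed,
            "original_auc": self.original_auc,
            "exceedance_fraction": self.exceedance_fraction,
            "mirna_dependent": self.mirna_dependent,
            "simulated_aucs": [float(a) for a in self.simulated_aucs],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# profile shuffling
# ---------------------------------------------------------------------------

def shuffle_profile(
    profile: pd.Series, scheme: ShuffleScheme, rng: np.random.Generator | int
) -> tuple[pd.Series, list[str]]:
    """One simulated profile plus the miRNA subset the variable sums
    should run over ("expressed" means value > 0)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    expressed = profile[profile > 0]
    if scheme.k > len(expressed):
        raise ValueError(
            f"k={scheme.k} exceeds the {len(expressed)} expressed miRNAs"
        )
    top = top_expressed(expressed, scheme.k)  # descending, deterministic ties
    top_values = profile.loc[top].to_numpy(dtype=float)

    if scheme.kind == "random_identity":
        pool = sorted(expressed.index)
        targets = [pool[i] for i in rng.choice(len(pool), size=scheme.k, replace=False)]
        out = pd.Series(0.0, index=profile.index)
        out.loc[targets] = top_values  # ordered values onto the random draw
        return out, targets

    out = profile.astype(float).copy()
    if scheme.kind == "within_top":
        fixed = 0
    elif scheme.kind == "within_top_fix_top_n":
        fixed = scheme.n_fixed
    else:  # within_top_fix_low_n: keep the n lowest of the top-k fixed
        fixed = scheme.n_fixed
        top = top[::-1]
        top_values = top_values[::-1]
    free = len(top) - fixed
    perm = rng.permutation(free)
    shuffled = top_values.copy()
    shuffled[fixed:] = top_values[fixed:][perm]
    out.loc[top] = shuffled
    subset = sorted(top)
    return out, subset


# ---------------------------------------------------------------------------
# fast single-variable kernel
# ---------------------------------------------------------------------------

@dataclass
class VariableInputs:
    """Pre-aligned inputs for repeated single-variable recomputation."""

    mirna_profile: pd.Series
    mrna_profile: pd.Series
    bs_utr: BindingSiteMatrix
    bs_cds: BindingSiteMatrix
    dbs_utr: BindingSiteMatrix
    dbs_cds: BindingSiteMatrix
    lengths: pd.DataFrame

    def __post_init__(self) -> None:
        genes = sorted(
            set(self.bs_utr.gene_ids) & set(self.bs_cds.gene_ids)
            & set(self.mrna_profile.index) & set(self.lengths.index)
        )
        if not genes:
            raise ValueError("no genes shared by all inputs")
        mirnas = list(self.bs_utr.values.index)
        self._genes = genes
        self._mirna_index = pd.Index(mirnas)
        self._mats = {
            "bs_utr": self.bs_utr.values.reindex(columns=genes).to_numpy(dtype=float),
            "bs_cds": self.bs_cds.values.reindex(index=mirnas, columns=genes).to_numpy(dtype=float),
            "dbs_utr": self.dbs_utr.values.reindex(index=mirnas, columns=genes).to_numpy(dtype=float),
            "dbs_cds": self.dbs_cds.values.reindex(index=mirnas, columns=genes).to_numpy(dtype=float),
        }
        self._g = self.mrna_profile.reindex(genes).to_numpy(dtype=float)
        self._L = {
            "L1": self.lengths["L1"].reindex(genes).to_numpy(dtype=float),
            "L2": self.lengths["L2"].reindex(genes).to_numpy(dtype=float),
        }

    @property
    def genes(self) -> list[str]:
        return self._genes

    def single_variable(
        self, name: str, profile: pd.Series, subset: Sequence[str]
    ) -> np.ndarray:
        """One named variable over all genes, as a vector.

        ``profile`` is the (possibly shuffled) miRNA expression series;
        ``subset`` the miRNAs the sum runs over.
        """
        if name not in VARIABLE_NAMES:
            raise KeyError(name)
        if name == "F9":
            return self._g.copy()
        if name in ("L1", "L2"):
            return self._L[name].copy()
        base = int(name[1])  # F1..F8 (+ optional 'd')
        mat_key = ("bs_utr" if base <= 4 else "bs_cds")
        if name.endswith("d"):
            mat_key = "d" + mat_key
        weighted = base in (1, 2, 5, 6)
        times_g = base in (1, 3, 5, 7)
        in_subset = self._mirna_index.isin(subset)
        if weighted:
            w = np.where(in_subset, profile.reindex(self._mirna_index).to_numpy(dtype=float), 0.0)
        else:
            w = in_subset.astype(float)
        val = w @ self._mats[mat_key]
        return val * self._g if times_g else val


# ---------------------------------------------------------------------------
# simulations
# ---------------------------------------------------------------------------

def _exceedance(sim: np.ndarray, original: float, strict: bool) -> float:
    if strict:
        return float(np.mean(sim > original))
    return float(np.mean(sim >= original))


def simulate_auc_distribution(
    variable_name: str,
    inputs: VariableInputs,
    labels: pd.Series,
    scheme: ShuffleScheme,
    n_sim: int = 1000,
    seed: int = 0,
    strict: bool = False,
) -> ShuffleResult:
    """Distribution of the variable's AUC under profile shuffling.

    ``labels`` is a per-gene UP/LOW/NS series; NS genes are ignored.
    Variables with no miRNA dependence (F9, L1, L2) yield a degenerate
    distribution equal to the original AUC, flagged via
    ``mirna_dependent=False``.
    """
    lab = labels.reindex(inputs.genes)
    keep = lab.isin([CALL_UP, CALL_LOW]).to_numpy()
    y = (lab[keep] == CALL_UP).to_numpy()

    profile = inputs.mirna_profile
    expressed = profile[profile > 0]
    orig_subset = top_expressed(expressed, min(scheme.k, len(expressed)))
    orig_scores = inputs.single_variable(variable_name, profile, orig_subset)
    original_auc = roc_auc(orig_scores[keep], y).auc

    if variable_name not in MIRNA_DEPENDENT:
        sims = np.full(n_sim, original_auc)
        return ShuffleResult(
            original_auc=original_auc, simulated_aucs=sims,
            exceedance_fraction=_exceedance(sims, original_auc, strict),
            scheme=scheme, seed=seed, variable=variable_name, mirna_dependent=False,
        )

    children = np.random.SeedSequence(seed).spawn(n_sim)
    sims = np.empty(n_sim)
    for i in range(n_sim):
        rng = np.random.default_rng(children[i])
        sim_profile, subset = shuffle_profile(profile, scheme, rng)
        scores = inputs.single_variable(variable_name, sim_profile, subset)
        sims[i] = roc_auc(scores[keep], y).auc
    return ShuffleResult(
        original_auc=original_auc, simulated_aucs=sims,
        exceedance_fraction=_exceedance(sims, original_auc, strict),
        scheme=scheme, seed=seed, variable=variable_name, mirna_dependent=True,
    )


def fixed_n_sweep(
    variable_name: str,
    inputs: VariableInputs,
    labels: pd.Series,
    scheme_family: str,
    n_values: Sequence[int],
    n_sim: int = 1000,
    seed: int = 0,
    k: int = 50,
    strict: bool = False,
) -> list[ShuffleResult]:
    """Hold-n-fixed sweep: shuffle the top-k while pinning an increasing
    number of top (or low) expressed miRNAs.

    ``scheme_family`` is ``within_top_fix_top_n`` or
    ``within_top_fix_low_n``; n = 0 reduces to the plain within-top
    shuffle and n = k to the identity (exceedance exactly 1).  On
    signal-bearing data the median simulated AUC is non-decreasing in n.
    """
    if scheme_family not in ("within_top_fix_top_n", "within_top_fix_low_n"):
        raise ValueError(f"unknown scheme family {scheme_family!r}")
    results = []
    for idx, n in enumerate(n_values):
        scheme = ShuffleScheme(kind=scheme_family, k=k, n_fixed=int(n))
        sub_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))
        results.append(
            simulate_auc_distribution(
                variable_name, inputs, labels, scheme,
                n_sim=n_sim, seed=sub_seed, strict=strict,
            )
        )
    return results


def sweep_summary(results: Sequence[ShuffleResult]) -> pd.DataFrame:
    """Boxplot-ready summary of a fixed-n sweep."""
    rows = []
    for r in results:
        q1, med, q3 = np.percentile(r.simulated_aucs, [25, 50, 75])
        rows.append({
            "variable": r.variable, "kind": r.scheme.kind, "n_fixed": r.scheme.n_fixed,
            "k": r.scheme.k, "original_auc": r.original_auc,
            "sim_q1": q1, "sim_median": med, "sim_q3": q3,
            "exceedance_fraction": r.exceedance_fraction,
        })
    return pd.DataFrame(rows)
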