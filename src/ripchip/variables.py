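"""The 19 per-gene variables modelling miRNA activity.

Each gene j is summarised by combinations of the binding-site count
matrix BS (and its density form dBS), the miRNA expression profile e_i
and the mRNA expression g_j of one IN sample, all on the linear scale:

    F1 = sum_i e_i * BS^utr_ij * g_j     F5 = the same on the CDS
    F2 = sum_i e_i * BS^utr_ij           F6 =  "
    F3 = sum_i BS^utr_ij * g_j           F7 =  "
    F4 = sum_i BS^utr_ij                 F8 =  "
    F1d..F4d, F5d..F8d: dBS in place of BS
    F9 = g_j;  L1 = 3'UTR length;  L2 = coding-region length

The sums run over a configurable miRNA subset (default: the top 50
expressed miRNAs of the source IN sample); miRNAs outside the subset
contribute nothing, which also makes the unweighted variables (F4, F4d,
F8, F8d) depend on the identity of the highly expressed miRNAs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import top_expressed
from .sequences import BindingSiteMatrix

VARIABLE_NAMES = (
    "F1", "F2", "F3", "F4", "F1d", "F2d", "F3d", "F4d",
    "F5", "F6", "F7", "F8", "F5d", "F6d", "F7d", "F8d",
    "F9", "L1", "L2",
)

#: variables whose value changes when the miRNA expression profile or the
#: expressed-miRNA subset changes
MIRNA_DEPENDENT = frozenset(
    ("F1", "F2", "F5", "F6", "F1d", "F2d", "F5d", "F6d",
     "F3", "F4", "F7", "F8", "F3d", "F4d", "F7d", "F8d")
)

DEFAULT_TOP_K = 50


@dataclass
class VariableTable:
    table: pd.DataFrame  # genes x 19 variables
    mirna_subset: list[str]
    source_sample: str | None = None

    def __getitem__(self, name: str) -> pd.Series:
        return self.table[name]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index_label="gene_id")
        meta = {"mirna_subset": self.mirna_subset, "source_sample": self.source_sample}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "VariableTable":
        path = Path(path)
        table = pd.read_csv(path, sep="\t", index_col="gene_id")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            table=table,
            mirna_subset=meta.get("mirna_subset", []),
            source_sample=meta.get("source_sample"),
        )


def _resolve_subset(mirna_profile: pd.Series, mirna_subset) -> list[str]:
    if mirna_subset is None:
        mirna_subset = min(DEFAULT_TOP_K, len(mirna_profile))
    if isinstance(mirna_subset, int):
        return top_expressed(mirna_profile, mirna_subset)
    return list(mirna_subset)


def _check_alignment(mirna_profile, bs_matrices, subset):
    rows = None
    for bs in bs_matrices:
        if rows is None:
            rows = list(bs.values.index)
        elif list(bs.values.index) != rows:
            raise ValueError("BS/dBS matrices have differently ordered miRNA rows")
    missing = [m for m in rows if m not in mirna_profile.index]
    if missing:
        raise ValueError(f"miRNAs without expression values: {', '.join(missing[:10])}")
    bad = [m for m in subset if m not in rows]
    if bad:
        raise ValueError(f"subset miRNAs absent from BS matrices: {', '.join(bad[:10])}")


def compute_variables(
    mirna_profile: pd.Series,
    mrna_profile: pd.Series,
    bs_utr: BindingSiteMatrix,
    bs_cds: BindingSiteMatrix,
    dbs_utr: BindingSiteMatrix,
    dbs_cds: BindingSiteMatrix,
    lengths: pd.DataFrame,
    mirna_subset: int | Sequence[str] | None = None,
    source_sample: str | None = None,
) -> VariableTable:
    """Compute the full 19-variable table for every gene with both regions.

    ``lengths`` has columns L1 (3'UTR length) and L2 (coding-region
    length) indexed by gene.  ``mirna_subset`` is a list of miRNA ids,
    an integer k (top-k expressed of ``mirna_profile``), or None for the
    default top 50.  Genes are the intersection of the matrix columns,
    the mRNA profile and the length table (genes missing either region
    are excluded).
    """
    subset = _resolve_subset(mirna_profile, mirna_subset)
    matrices = (bs_utr, bs_cds, dbs_utr, dbs_cds)
    _check_alignment(mirna_profile, matrices, subset)

    genes = sorted(
        set(bs_utr.gene_ids) & set(bs_cds.gene_ids)
        & set(mrna_profile.index) & set(lengths.index)
    )
    if not genes:
        raise ValueError("no genes shared by all inputs")

    e = mirna_profile.reindex(subset).to_numpy(dtype=float)
    g = mrna_profile.reindex(genes).to_numpy(dtype=float)
    mats = {name: m.values.reindex(index=subset, columns=genes).to_numpy(dtype=float)
            for name, m in zip(("bs_utr", "bs_cds", "dbs_utr", "dbs_cds"), matrices)}

    cols: dict[str, np.ndarray] = {}
    for prefix, weighted, plain in (("utr", ("F1", "F2", "F3", "F4"), "bs_utr"),
                                    ("cds", ("F5", "F6", "F7", "F8"), "bs_cds")):
        for suffix in ("", "d"):
            mat = mats[("d" if suffix else "") + plain]
            ew = e @ mat            # sum_i e_i * M_ij
            uw = mat.sum(axis=0)    # sum_i M_ij
            n1, n2, n3, n4 = weighted
            cols[n1 + suffix] = ew * g
            cols[n2 + suffix] = ew
            cols[n3 + suffix] = uw * g
            cols[n4 + suffix] = uw
    cols["F9"] = g
    cols["L1"] = lengths["L1"].reindex(genes).to_numpy(dtype=float)
    cols["L2"] = lengths["L2"].reindex(genes).to_numpy(dtype=float)

    table = pd.DataFrame({name: cols[name] for name in VARIABLE_NAMES},
                         index=pd.Index(genes, name="gene_id"))
    return VariableTable(table=table, mirna_subset=subset, source_sample=source_sample)


def compute_single_variable(
    name: str,
    mirna_profile: pd.Series,
    mrna_profile: pd.Series,
    bs_utr: BindingSiteMatrix,
    bs_cds: BindingSiteMatrix,
    dbs_utr: BindingSiteMatrix,
    dbs_cds: BindingSiteMatrix,
    lengths: pd.DataFrame,
    mirna_subset: int | Sequence[str] | None = None,
) -> pd.Series:
    """One named variable over all genes; used by the shuffling simulations
    where a single variable is recomputed for thousands of profiles."""
    if name not in VARIABLE_NAMES:
        raise KeyError(name)
    vt = compute_variables(
        mirna_profile, mrna_profile, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
        mirna_subset=mirna_subset,
    )
    return vt[name]


def variable_correlation_matrix(v: VariableTable) -> pd.DataFrame:
    """Pearson correlation matrix of the 19 variables across genes.

    Zero-variance columns yield NaN rows/columns (undefined, not 0); the
    diagonal is exactly 1 for well-defined columns.
    """
    if len(v.table) < 3:
        raise ValueError("need at least three genes for a correlation matrix")
    corr = v.table.corr(method="pearson")
    defined = v.table.std() > 0
    for name in corr.index:
        if defined[name]:
            corr.loc[name, name] = 1.0
        else:
            corr.loc[name, :] = np.nan
            corr.loc[:, name] = np.nan
    return corr
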