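"""Expression matrices for RIP-Chip samples: loading, quantile
normalization, replicate averaging, correlation-distance clustering.

A RIP experiment yields three fractions per replicate: the input lysate
(IN), the immunoprecipitated fraction (IP) and the unbound flow-through
(FT).  Intensities are kept on the linear scale throughout the
expression-weighted variable formulas; a log2(x+1) transform is applied
only inside the clustering step, where correlation structure rather
than absolute intensity is of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

ROLE_IN = "IN"
ROLE_IP = "IP"
ROLE_FT = "FT"
ROLES = (ROLE_IN, ROLE_IP, ROLE_FT)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    role: str
    antibody: str = "other"  # AGO2, GW182 or other
    experiment: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown sample role {self.role!r}")


@dataclass
class ExpressionMatrix:
    """Feature x sample intensity matrix with per-sample metadata."""

    values: pd.DataFrame  # rows = features, columns = sample_ids
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        triples = [(s.role, s.antibody, s.experiment) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("(role, antibody, experiment) triples must be unique")
        if list(self.values.columns) != ids:
            raise ValueError("value columns do not match sample metadata order")
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("missing values are not allowed; clean the input first")
        if (vals < 0).any():
            raise ValueError("negative intensities are not allowed")

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset_roles(self, roles: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.samples if s.role in roles]
        return ExpressionMatrix(
            values=self.values[[s.sample_id for s in keep]].copy(), samples=keep
        )

    def column(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
        pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "role": s.role,
                    "antibody": s.antibody,
                    "experiment": s.experiment,
                }
                for s in self.samples
            ]
        ).to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="feature_id")
        meta = pd.read_csv(meta_path, sep="\t")
        samples = [
            SampleMeta(
                sample_id=str(r.sample_id),
                role=str(r.role),
                antibody=str(r.antibody),
                experiment=int(r.experiment),
            )
            for r in meta.itertuples(index=False)
        ]
        values = values[[s.sample_id for s in samples]]
        return cls(values=values, samples=samples)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank mean distribution.

    Each column is sorted, per-rank cross-sample means are computed, and
    each column's values are replaced by the mean of their rank.  Ties
    keep their original relative order (stable sort), which makes the
    transform idempotent.  A single-column matrix is returned unchanged.
    """
    vals = m.values.to_numpy(dtype=float)
    if vals.shape[1] <= 1:
        return ExpressionMatrix(values=m.values.copy(), samples=list(m.samples))
    order = np.argsort(vals, axis=0, kind="stable")
    ranked = np.take_along_axis(vals, order, axis=0)
    rank_means = ranked.mean(axis=1)
    out = np.empty_like(vals)
    np.put_along_axis(out, order, rank_means[:, None], axis=0)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=values, samples=list(m.samples))


def average_replicates(
    m: ExpressionMatrix, group_by: Sequence[str] = ("role", "antibody")
) -> ExpressionMatrix:
    """Average instrumental replicates: one output column per metadata group.

    ``group_by`` names SampleMeta fields; samples sharing the same tuple
    of values are averaged feature-wise.  Output sample ids join the
    group key with underscores; the experiment index of the merged
    sample is the smallest one in the group.
    """
    groups: dict[tuple, list[SampleMeta]] = {}
    for s in m.samples:
        key = tuple(getattr(s, k) for k in group_by)
        groups.setdefault(key, []).append(s)
    out_cols = {}
    out_meta = []
    for key, members in groups.items():
        if not members:
            raise ValueError("empty replicate group")
        sample_id = "_".join(str(k) for k in key)
        out_cols[sample_id] = m.values[[s.sample_id for s in members]].mean(axis=1)
        proto = members[0]
        out_meta.append(
            SampleMeta(
                sample_id=sample_id,
                role=proto.role,
                antibody=proto.antibody,
                experiment=min(s.experiment for s in members),
            )
        )
    values = pd.DataFrame(out_cols)
    return ExpressionMatrix(values=values, samples=out_meta)


@dataclass
class ClusterResult:
    """Average-linkage dendrogram over samples at distance 1 - Pearson r."""

    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]
    distance: pd.DataFrame  # pairwise 1 - correlation

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic_distance(self, a: str, b: str) -> float:
        d = sch.cophenet(self.linkage)
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(squareform(d)[i, j])


def correlation_distance_cluster(
    m: ExpressionMatrix, log_transform: bool = True
) -> ClusterResult:
    """Hierarchically cluster samples with dist = 1 - Pearson correlation,
    average linkage (UPGMA).

    ``log_transform`` applies log2(x+1) before computing correlations;
    Pearson correlation is otherwise dominated by the brightest features.
    Raises if fewer than two samples or if a sample has zero variance
    (correlation undefined), naming the offending sample.
    """
    if len(m.samples) < 2:
        raise ValueError("clustering needs at least two samples")
    vals = m.values.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    sd = vals.std(axis=0)
    for sid, s in zip(m.values.columns, sd):
        if s == 0:
            raise ValueError(f"sample {sid!r} has zero variance; correlation undefined")
    corr = np.corrcoef(vals, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    condensed = squareform(dist, checks=False)
    linkage = sch.linkage(condensed, method="average")
    dist_df = pd.DataFrame(dist, index=m.values.columns, columns=m.values.columns)
    return ClusterResult(linkage=linkage, sample_ids=list(m.values.columns), distance=dist_df)


def top_expressed(profile: pd.Series, n: int) -> list[str]:
    """The ``n`` highest-expressed feature ids, descending.

    Ties break on the lexicographically smaller id so the selection is
    deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(profile):
        raise ValueError(f"n={n} exceeds the {len(profile)} available features")
    idx = np.lexsort((np.asarray(profile.index), -profile.to_numpy(dtype=float)))
    return [profile.index[i] for i in idx[:n]]
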