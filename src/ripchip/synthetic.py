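"""Synthetic RIP-Chip studies with planted signal.

The generator emulates the statistical structure the analysis relies
on, so every stage is testable without any external download:

* region lengths are log-normal (3'UTR median ~1 kb, CDS median ~1.5 kb);
* the miRNA IN profile is heavy-tailed with one dominant species
  holding a configurable share (default 60%) of the total mass;
* the mRNA IN profile is log-normal;
* binding-site counts are Poisson with rate proportional to region
  length times a per-miRNA seed propensity, which induces the
  count-vs-length correlation expected of any site scanner;
* each gene's UP/LOW/NS label is drawn from a logistic model on the
  z-scored driver variable (F6 for the AGO2-like mode, L2 for the
  GW182-like mode; an optional second driver adds an independent
  signal), P(UP) = sigmoid(alpha + beta * z), P(LOW) mirrored with
  -beta;
* IP intensities are the IN profile times exp(ip_shift * label_sign +
  noise); FT is mirrored with the opposite shift.  Replicated over
  n_experiments.

``null`` mode draws decoy labels at the base rate (beta = 0) and builds
IP/FT as pure noise around IN (no shift), so enrichment calls should be
at the false-positive floor while the labels remain available as an
uninformative reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleMeta, top_expressed
from .sequences import BindingSiteMatrix, MirnaSeed, count_seed_sites, density_matrix
from .variables import VARIABLE_NAMES

logger = logging.getLogger(__name__)

MODES = ("ago2_like", "gw182_like", "null")

_MODE_DRIVER = {"ago2_like": "F6", "gw182_like": "L2", "null": None}
_MODE_BETA = {"ago2_like": 1.5, "gw182_like": 2.0, "null": 0.0}


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 2000
    n_mirnas: int = 50
    mode: str = "ago2_like"
    driver: str | None = None          # resolved from mode when None
    effect_beta: float | None = None   # logistic slope; mode default when None
    driver2: str | None = None         # optional second, independent signal
    effect_beta2: float = 0.0
    dominant_mirna_share: float = 0.6
    ip_shift: float = 1.0              # log-scale IP-vs-FT shift for labelled genes
    noise_sigma: float = 0.25
    n_experiments: int = 3
    alpha: float = -2.0                # logistic intercept (label base rate)
    top_k: int = 50
    min_class_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.dominant_mirna_share < 1:
            raise ValueError("dominant_mirna_share must be in [0, 1)")
        if self.n_experiments < 2:
            raise ValueError("need at least two experiments")
        if self.effect_beta is not None and self.effect_beta < 0:
            raise ValueError("effect_beta must be non-negative")
        if self.driver is not None and self.driver not in VARIABLE_NAMES:
            raise ValueError(f"unknown driver variable {self.driver!r}")

    @property
    def resolved_driver(self) -> str | None:
        return self.driver if self.driver is not None else _MODE_DRIVER[self.mode]

    @property
    def resolved_beta(self) -> float:
        if self.mode == "null":
            return 0.0
        return self.effect_beta if self.effect_beta is not None else _MODE_BETA[self.mode]

    @property
    def resolved_ip_shift(self) -> float:
        return 0.0 if self.mode == "null" else self.ip_shift


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    bs_utr: BindingSiteMatrix
    bs_cds: BindingSiteMatrix
    dbs_utr: BindingSiteMatrix
    dbs_cds: BindingSiteMatrix
    lengths: pd.DataFrame              # columns L1, L2, index gene_id
    mirna_profile: pd.Series           # IN miRNA expression
    mrna_profile: pd.Series            # IN mRNA expression
    expression: ExpressionMatrix       # IN/IP/FT mRNA intensities per experiment
    true_labels: pd.Series             # UP/LOW/NS

    def write(self, out_dir: str | Path) -> None:
        """Write the dataset in the same TSV formats the loaders read."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bs_utr.to_tsv(out / "bs_utr3.tsv")
        self.bs_cds.to_tsv(out / "bs_cds.tsv")
        self.dbs_utr.to_tsv(out / "dbs_utr3.tsv")
        self.dbs_cds.to_tsv(out / "dbs_cds.tsv")
        self.lengths.to_csv(out / "lengths.tsv", sep="\t", index_label="gene_id")
        self.mirna_profile.rename("expression").to_csv(
            out / "mirna_profile.tsv", sep="\t", index_label="mirna_id")
        self.mrna_profile.rename("expression").to_csv(
            out / "mrna_profile.tsv", sep="\t", index_label="gene_id")
        self.expression.to_tsv(out / "expression.tsv", out / "samples.tsv")
        self.true_labels.rename("label").to_csv(
            out / "true_labels.tsv", sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, in_dir: str | Path, config: SyntheticConfig | None = None) -> "SyntheticDataset":
        d = Path(in_dir)
        return cls(
            config=config or SyntheticConfig(),
            bs_utr=BindingSiteMatrix.read_tsv(d / "bs_utr3.tsv"),
            bs_cds=BindingSiteMatrix.read_tsv(d / "bs_cds.tsv"),
            dbs_utr=BindingSiteMatrix.read_tsv(d / "dbs_utr3.tsv"),
            dbs_cds=BindingSiteMatrix.read_tsv(d / "dbs_cds.tsv"),
            lengths=pd.read_csv(d / "lengths.tsv", sep="\t", index_col="gene_id"),
            mirna_profile=pd.read_csv(d / "mirna_profile.tsv", sep="\t",
                                      index_col="mirna_id")["expression"],
            mrna_profile=pd.read_csv(d / "mrna_profile.tsv", sep="\t",
                                     index_col="gene_id")["expression"],
            expression=ExpressionMatrix.read_tsv(d / "expression.tsv", d / "samples.tsv"),
            true_labels=pd.read_csv(d / "true_labels.tsv", sep="\t",
                                    index_col="gene_id")["label"],
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _single_variable_vector(name, e, g, mats, L1, L2, subset_mask) -> np.ndarray:
    if name == "F9":
        return g
    if name == "L1":
        return L1
    if name == "L2":
        return L2
    base = int(name[1])
    key = ("bs_utr" if base <= 4 else "bs_cds")
    if name.endswith("d"):
        key = "d" + key
    w = np.where(subset_mask, e, 0.0) if base in (1, 2, 5, 6) else subset_mask.astype(float)
    val = w @ mats[key]
    return val * g if base in (1, 3, 5, 7) else val


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete synthetic study from config + seed.

    Deterministic: the same config and seed give identical datasets.
    Raises if the logistic labelling cannot produce at least
    ``min_class_size`` genes per class even after widening the
    intercept.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    mirnas = [f"miR-{i:03d}" for i in range(config.n_mirnas)]

    # region lengths, log-normal, floored at the 50 nt selection cutoff
    L1 = np.maximum(np.round(rng.lognormal(np.log(1000.0), 0.7, config.n_genes)), 50)
    L2 = np.maximum(np.round(rng.lognormal(np.log(1500.0), 0.6, config.n_genes)), 50)
    lengths = pd.DataFrame({"L1": L1, "L2": L2}, index=pd.Index(genes, name="gene_id"))

    # heavy-tailed miRNA profile with one dominant species
    total_mass = 1e5
    rest = rng.lognormal(0.0, 1.2, config.n_mirnas - 1)
    rest = rest / rest.sum() * (1.0 - config.dominant_mirna_share)
    weights = np.concatenate([[config.dominant_mirna_share], rest])
    mirna_profile = pd.Series(weights * total_mass, index=pd.Index(mirnas, name="mirna_id"))

    # mRNA IN profile, log-normal
    mrna_profile = pd.Series(
        rng.lognormal(np.log(500.0), 1.0, config.n_genes),
        index=pd.Index(genes, name="gene_id"),
    )

    # binding-site counts: Poisson, rate ~ length x per-miRNA propensity
    base_rate = 1.0 / 4**7  # chance rate of a 7-mer site per base
    mats = {}
    for key, lens in (("bs_utr", L1), ("bs_cds", L2)):
        propensity = base_rate * rng.lognormal(0.0, 0.5, config.n_mirnas)
        rate = np.outer(propensity, lens)
        counts = rng.poisson(rate).astype(float)
        mats[key] = counts
        mats["d" + key] = counts / lens[None, :]

    def bsm(key, region, mode):
        return BindingSiteMatrix(
            values=pd.DataFrame(mats[key], index=pd.Index(mirnas, name="mirna_id"),
                                columns=genes),
            region=region, mode=mode,
        )

    bs_utr = bsm("bs_utr", "utr3", "count")
    bs_cds = bsm("bs_cds", "cds", "count")
    dbs_utr = bsm("dbs_utr", "utr3", "density")
    dbs_cds = bsm("dbs_cds", "cds", "density")

    # labels from the logistic model on the z-scored driver(s)
    subset = top_expressed(mirna_profile, min(config.top_k, config.n_mirnas))
    subset_mask = np.isin(mirnas, subset)
    e = mirna_profile.to_numpy(dtype=float)
    g = mrna_profile.to_numpy(dtype=float)
    eta = np.zeros(config.n_genes)
    beta = config.resolved_beta
    driver = config.resolved_driver
    if driver is not None and beta > 0:
        eta += beta * _zscore(
            _single_variable_vector(driver, e, g, mats, L1, L2, subset_mask))
    if config.driver2 is not None and config.effect_beta2 > 0:
        eta += config.effect_beta2 * _zscore(
            _single_variable_vector(config.driver2, e, g, mats, L1, L2, subset_mask))

    labels = None
    alpha = config.alpha
    for attempt in range(4):
        p_up = _sigmoid(alpha + eta)
        p_low = _sigmoid(alpha - eta)
        u = rng.uniform(size=config.n_genes)
        cand = np.where(u < p_up, "UP", np.where(u < p_up + p_low, "LOW", "NS"))
        n_up = int((cand == "UP").sum())
        n_low = int((cand == "LOW").sum())
        if min(n_up, n_low) >= config.min_class_size:
            labels = cand
            break
        logger.info("label draw gave %d UP / %d LOW; widening alpha %.2f -> %.2f",
                    n_up, n_low, alpha, alpha + 0.4)
        alpha += 0.4
    if labels is None:
        raise ValueError(
            f"could not obtain {config.min_class_size} genes per class; "
            "increase n_genes or effect size"
        )
    true_labels = pd.Series(labels, index=pd.Index(genes, name="gene_id"), name="label")
    sign = np.where(labels == "UP", 1.0, np.where(labels == "LOW", -1.0, 0.0))

    # IN / IP / FT intensities, multiplicative log-scale enrichment + noise
    shift = config.resolved_ip_shift
    cols = {}
    meta = []
    for exp in range(1, config.n_experiments + 1):
        noise = lambda: rng.normal(0.0, config.noise_sigma, config.n_genes)
        cols[f"IN{exp}"] = g * np.exp(noise())
        cols[f"IP{exp}"] = g * np.exp(shift * sign + noise())
        cols[f"FT{exp}"] = g * np.exp(-shift * sign + noise())
        for role in ("IN", "IP", "FT"):
            meta.append(SampleMeta(sample_id=f"{role}{exp}", role=role,
                                   antibody="AGO2" if config.mode == "ago2_like" else
                                   ("GW182" if config.mode == "gw182_like" else "other"),
                                   experiment=exp))
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    values = values[[m.sample_id for m in meta]]
    expression = ExpressionMatrix(values=values, samples=meta)

    return SyntheticDataset(
        config=config, bs_utr=bs_utr, bs_cds=bs_cds, dbs_utr=dbs_utr, dbs_cds=dbs_cds,
        lengths=lengths, mirna_profile=mirna_profile, mrna_profile=mrna_profile,
        expression=expression, true_labels=true_labels,
    )


# ---------------------------------------------------------------------------
# sequence generation with planted sites
# ---------------------------------------------------------------------------

def generate_sequences(
    lengths: Mapping[str, int] | pd.Series,
    seeds: Sequence[MirnaSeed],
    planted_sites: Mapping[tuple[str, str], int],
    gc_content: float = 0.5,
    seed: int = 0,
    max_tries: int = 200,
) -> dict[str, str]:
    """Random sequences carrying an exact number of seed sites.

    ``planted_sites`` maps (mirna_id, gene_id) to the number of binding
    sites to plant.  Background is resampled until it contains no
    spurious matches for any of the given seeds, then sites are written
    at non-overlapping random positions and the whole gene re-verified,
    so the detected count equals the planted count exactly.
    """
    lengths = dict(pd.Series(lengths).astype(int).items())
    seed_by_id = {s.mirna_id: s for s in seeds}
    for (mid, gid), cnt in planted_sites.items():
        if mid not in seed_by_id:
            raise ValueError(f"unknown miRNA {mid!r} in planted_sites")
        if gid not in lengths:
            raise ValueError(f"unknown gene {gid!r} in planted_sites")
        if cnt < 0:
            raise ValueError("planted counts must be non-negative")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    alphabet = np.array(list("ACGT"))

    out: dict[str, str] = {}
    for gid, length in lengths.items():
        wanted = {mid: planted_sites.get((mid, gid), 0) for mid in seed_by_id}
        total_site_len = sum(len(seed_by_id[mid].site) * c for mid, c in wanted.items())
        if total_site_len > length:
            raise ValueError(f"cannot plant {total_site_len} site bases in gene "
                             f"{gid!r} of length {length}")
        for attempt in range(max_tries):
            chars = rng.choice(alphabet, size=length, p=p)
            seq = "".join(chars)
            if any(count_seed_sites(seq, s) for s in seeds):
                continue  # spurious background match; resample
            seq = _plant(seq, wanted, seed_by_id, rng)
            if seq is not None and all(
                count_seed_sites(seq, seed_by_id[mid]) == cnt
                for mid, cnt in wanted.items()
            ):
                out[gid] = seq
                break
        else:
            raise ValueError(f"could not generate sequence for gene {gid!r} "
                             f"after {max_tries} tries")
    return out


def _plant(seq: str, wanted, seed_by_id, rng) -> str | None:
    """Write the requested sites at random non-overlapping positions."""
    occupied: list[tuple[int, int]] = []
    chars = list(seq)
    for mid in sorted(wanted):
        site = seed_by_id[mid].site
        for _ in range(wanted[mid]):
            placed = False
            for _try in range(200):
                start = int(rng.integers(0, len(seq) - len(site) + 1))
                span = (start, start + len(site))
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    occupied.append(span)
                    chars[span[0]:span[1]] = site
                    placed = True
                    break
            if not placed:
                return None
    return "".join(chars)
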