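"""Gene-region sequences and miRNA seed binding-site matrices.

A miRNA recognises its targets mainly through its *seed*, nucleotides
~2-8 of the mature strand.  This module selects one representative
sequence per gene and region (3'UTR or coding region), scans it for
exact Watson-Crick matches to the reverse complement of each seed, and
assembles the miRNA x gene binding-site count matrix ``BS`` and its
per-base density counterpart ``dBS`` (counts divided by region length).

Seed definitions supported (``kind`` of :meth:`MirnaSeed.from_mature`):

``6mer``
    mature positions 2-7, exact reverse-complement match.
``7mer-m8`` (default)
    mature positions 2-8.
``8mer``
    positions 2-8 plus an adenine on the target opposite position 1
    (the canonical 8mer site: the 7mer-m8 site followed by ``A``).

Overlapping occurrences are counted: every start position is tested
independently.  ``N`` bases never match.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGION_UTR3 = "utr3"
REGION_CDS = "cds"
REGIONS = (REGION_UTR3, REGION_CDS)

MIN_SEQUENCE_LENGTH = 50  # shorter regions are discarded (inclusive floor)

_VALID_CHARS = frozenset("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


class InvalidSeedError(ValueError):
    """Raised when a seed string is unusable for matching."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence for a (gene, region) pair.

    ``record_id`` is the transcript/sequence identifier used only to
    break ties when several equally long sequences exist for a gene.
    """

    gene_id: str
    region: str
    sequence: str
    record_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_valid(self) -> bool:
        return self.region in REGIONS and set(self.sequence) <= _VALID_CHARS


@dataclass(frozen=True)
class MirnaSeed:
    """A miRNA seed, stored 5'->3' in DNA alphabet (U already mapped to T).

    Matching scans the target for the reverse complement of ``seed``.
    """

    mirna_id: str
    seed: str

    def __post_init__(self) -> None:
        seed = self.seed.upper().replace("U", "T")
        object.__setattr__(self, "seed", seed)
        if len(seed) < 6:
            raise InvalidSeedError(
                f"seed for {self.mirna_id!r} has length {len(seed)} < 6"
            )
        if len(seed) > 8:
            raise InvalidSeedError(
                f"seed for {self.mirna_id!r} has length {len(seed)} > 8"
            )
        if not set(seed) <= set("ACGT"):
            raise InvalidSeedError(f"seed for {self.mirna_id!r} contains non-ACGU characters")

    @property
    def site(self) -> str:
        """The target-site string matched on the mRNA (reverse complement)."""
        return reverse_complement(self.seed)

    @classmethod
    def from_mature(cls, mirna_id: str, mature: str, kind: str = "7mer-m8") -> "MirnaSeed":
        """Extract the seed from a mature miRNA sequence (5'->3').

        The 8mer seed is encoded by replacing position 1 with ``T`` so that
        the reverse complement carries the required target adenine at its
        3' end.
        """
        mature = mature.upper().replace("U", "T")
        if kind == "6mer":
            if len(mature) < 7:
                raise InvalidSeedError(f"mature {mirna_id!r} too short for 6mer seed")
            return cls(mirna_id, mature[1:7])
        if kind == "7mer-m8":
            if len(mature) < 8:
                raise InvalidSeedError(f"mature {mirna_id!r} too short for 7mer-m8 seed")
            return cls(mirna_id, mature[1:8])
        if kind == "8mer":
            if len(mature) < 8:
                raise InvalidSeedError(f"mature {mirna_id!r} too short for 8mer seed")
            return cls(mirna_id, "T" + mature[1:8])
        raise InvalidSeedError(f"unknown seed kind {kind!r}")


@dataclass
class SequenceSet:
    """Selected sequences, one per (gene, region)."""

    records: dict  # region -> {gene_id -> SequenceRecord}

    def genes(self, region: str) -> list[str]:
        return sorted(self.records.get(region, {}))

    def genes_both_regions(self) -> list[str]:
        """Genes with both a 3'UTR and a coding sequence retained."""
        return sorted(
            set(self.records.get(REGION_UTR3, {})) & set(self.records.get(REGION_CDS, {}))
        )

    def get(self, gene_id: str, region: str) -> SequenceRecord:
        return self.records[region][gene_id]

    def lengths(self, region: str) -> pd.Series:
        recs = self.records.get(region, {})
        return pd.Series({g: r.length for g, r in recs.items()}, dtype=float).sort_index()


@dataclass
class BindingSiteMatrix:
    """miRNA x gene matrix of binding-site counts or per-base densities."""

    values: pd.DataFrame  # rows = miRNAs, columns = genes
    region: str
    mode: str  # "count" or "density"

    def __post_init__(self) -> None:
        if self.mode not in ("count", "density"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("BindingSiteMatrix labels must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("BindingSiteMatrix values must be non-negative")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a sidecar JSON recording region/mode."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="mirna_id")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"region": self.region, "mode": self.mode}) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BindingSiteMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="mirna_id")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values=values, region=meta["region"], mode=meta["mode"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def select_sequences(records: Iterable[SequenceRecord]) -> SequenceSet:
    """Pick one representative sequence per (gene, region).

    When several sequences exist for the same gene and region, the
    longest one is retained; ties break on the lexicographically
    smallest ``record_id`` (then sequence).  Sequences shorter than
    ``MIN_SEQUENCE_LENGTH`` (50 nt, inclusive) are dropped, as are
    records with characters outside A/C/G/T/N (logged warning).
    """
    selected: dict[str, dict[str, SequenceRecord]] = {r: {} for r in REGIONS}
    for rec in records:
        if not rec.is_valid():
            logger.warning(
                "rejecting malformed record %s/%s (%s)", rec.gene_id, rec.region, rec.record_id
            )
            continue
        if rec.length < MIN_SEQUENCE_LENGTH:
            continue
        best = selected[rec.region].get(rec.gene_id)
        if best is None or _selection_key(rec) < _selection_key(best):
            selected[rec.region][rec.gene_id] = rec
    return SequenceSet(records=selected)


def _selection_key(rec: SequenceRecord) -> tuple:
    # longest first; ties by record id then sequence, ascending
    return (-rec.length, rec.record_id, rec.sequence)


def count_seed_sites(sequence: str, seed: MirnaSeed) -> int:
    """Count (overlapping) exact matches of the seed's target site.

    Every start position is tested independently, so a run of identical
    bases yields one match per start.  ``N`` never matches.
    """
    site = seed.site
    count = 0
    start = sequence.find(site)
    while start != -1:
        count += 1
        start = sequence.find(site, start + 1)
    return count


def build_bs_matrix(
    seqs: SequenceSet,
    seeds: Sequence[MirnaSeed],
    region: str,
    genes: Sequence[str] | None = None,
) -> BindingSiteMatrix:
    """Build the count-mode binding-site matrix for one region.

    ``genes`` restricts/orders the columns; genes requested but missing
    a sequence are omitted and reported via a logged warning.  miRNAs
    sharing an identical seed are kept as separate (identical) rows:
    downstream expression weighting differs per miRNA.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    available = seqs.records.get(region, {})
    if genes is None:
        cols = sorted(available)
    else:
        missing = [g for g in genes if g not in available]
        if missing:
            logger.warning(
                "%d gene(s) without %s sequence omitted from BS matrix: %s",
                len(missing), region, ", ".join(missing[:10]),
            )
        cols = [g for g in genes if g in available]
    mirna_ids = [s.mirna_id for s in seeds]
    if len(set(mirna_ids)) != len(mirna_ids):
        raise ValueError("duplicate miRNA ids in seed list")
    data = np.zeros((len(seeds), len(cols)), dtype=int)
    for i, seed in enumerate(seeds):
        for j, gene in enumerate(cols):
            data[i, j] = count_seed_sites(available[gene].sequence, seed)
    values = pd.DataFrame(data, index=pd.Index(mirna_ids, name="mirna_id"), columns=cols)
    return BindingSiteMatrix(values=values, region=region, mode="count")


def density_matrix(
    bs: BindingSiteMatrix, lengths: Mapping[str, float] | pd.Series
) -> BindingSiteMatrix:
    """Convert a count matrix to per-base densities: dBS_ij = BS_ij / L_j."""
    if bs.mode != "count":
        raise ValueError("density_matrix expects a count-mode matrix")
    lengths = pd.Series(lengths, dtype=float)
    missing = [g for g in bs.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"no length for gene(s): {', '.join(missing[:10])}")
    lens = lengths.reindex(bs.gene_ids)
    if (lens <= 0).any():
        bad = list(lens.index[lens <= 0])
        raise ValueError(f"non-positive length for gene(s): {', '.join(bad[:10])}")
    values = bs.values / lens
    return BindingSiteMatrix(values=values, region=bs.region, mode="density")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_region_fasta(path: str | Path, region: str) -> list[SequenceRecord]:
    """Read a FASTA of region sequences.

    Headers are ``>gene_id`` or ``>gene_id|record_id``; anything after
    whitespace is ignored.  Sequences are uppercased; U is mapped to T.
    """
    records: list[SequenceRecord] = []
    gene_id = record_id = None
    chunks: list[str] = []

    def flush() -> None:
        if gene_id is not None:
            seq = "".join(chunks).upper().replace("U", "T")
            records.append(SequenceRecord(gene_id, region, seq, record_id or ""))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            head = line[1:].split()[0]
            gene_id, _, record_id = head.partition("|")
            chunks = []
        else:
            chunks.append(line)
    flush()
    return records


def read_seeds(path: str | Path, kind: str = "7mer-m8") -> list[MirnaSeed]:
    """Read miRNA seeds from a two-column TSV (mirna_id, seed) or a FASTA
    of mature sequences (seed extracted per ``kind``)."""
    text = Path(path).read_text()
    seeds: list[MirnaSeed] = []
    if text.lstrip().startswith(">"):
        name = None
        chunks: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seeds.append(MirnaSeed.from_mature(name, "".join(chunks), kind))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            seeds.append(MirnaSeed.from_mature(name, "".join(chunks), kind))
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed seed line: {line!r}")
            if fields[0] == "mirna_id":  # header
                continue
            seeds.append(MirnaSeed(fields[0], fields[1]))
    return seeds


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
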