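import numpy as np
import pandas as pd
import pytest

from ripchip.sequences import (
    BindingSiteMatrix,
    InvalidSeedError,
    MirnaSeed,
    SequenceRecord,
    build_bs_matrix,
    count_seed_sites,
    density_matrix,
    read_region_fasta,
    read_seeds,
    reverse_complement,
    select_sequences,
    write_fasta,
)

from conftest import naive_site_scan


def rec(gene, seq, region="utr3", rid=""):
    return SequenceRecord(gene, region, seq, rid)


class TestSelectSequences:
    def test_longest_sequence_retained(self):
        records = [rec("G", "A" * 60), rec("G", "C" * 120)]
        out = select_sequences(records)
        assert out.get("G", "utr3").sequence == "C" * 120

    def test_length_floor_is_inclusive_at_50(self):
        out = select_sequences([rec("A", "A" * 49), rec("B", "A" * 50)])
        assert out.genes("utr3") == ["B"]
        assert out.get("B", "utr3").length == 50

    def test_tie_breaks_on_record_id(self):
        records = [rec("G", "A" * 60, rid="tx2"), rec("G", "C" * 60, rid="tx1")]
        assert select_sequences(records).get("G", "utr3").record_id == "tx1"

    def test_malformed_characters_rejected_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = select_sequences([rec("G", "ACGTX" * 20)])
        assert out.genes("utr3") == []
        assert "rejecting" in caplog.text

    def test_empty_input_gives_empty_set(self):
        out = select_sequences([])
        assert out.genes("utr3") == [] and out.genes("cds") == []

    def test_both_region_universe(self):
        records = [rec("A", "A" * 60), rec("B", "A" * 60),
                   rec("A", "A" * 60, region="cds")]
        assert select_sequences(records).genes_both_regions() == ["A"]


class TestSeeds:
    def test_seed_kinds_from_mature(self):
        mature = "UAGCUUAUCAGACUGAUGUUGA"  # 22 nt
        assert MirnaSeed.from_mature("m", mature, "6mer").seed == "AGCTTA"
        assert MirnaSeed.from_mature("m", mature, "7mer-m8").seed == "AGCTTAT"
        assert MirnaSeed.from_mature("m", mature, "8mer").seed == "TAGCTTAT"

    def test_8mer_site_ends_in_adenine(self):
        seed = MirnaSeed.from_mature("m", "UAGCUUAUCAG", "8mer")
        assert seed.site == reverse_complement("AGCTTAT") + "A"

    def test_short_seed_rejected(self):
        with pytest.raises(InvalidSeedError):
            MirnaSeed("m", "ACGTA")

    def test_u_mapped_to_t(self):
        assert MirnaSeed("m", "ACGUACG").seed == "ACGTACG"


class TestCountSeedSites:
    def test_planted_single_site(self):
        seed = MirnaSeed("m", "ACGGCAT")
        background = "T" * 30 + seed.site + "T" * 30
        assert count_seed_sites(background, seed) == 1

    def test_overlapping_poly_a_counts_every_start(self):
        # 7-mer whose site is AAAAAAA inside AAAAAAAAAA: brute force gives 4
        seed = MirnaSeed("m", "TTTTTTT")
        assert seed.site == "AAAAAAA"
        assert naive_site_scan("A" * 10, "AAAAAAA") == 4
        assert count_seed_sites("A" * 10, seed) == 4

    def test_no_occurrence(self):
        assert count_seed_sites("G" * 50, MirnaSeed("m", "GGGGGGG")) == 0

    def test_n_never_matches(self):
        seed = MirnaSeed("m", "TTTTTTT")
        assert count_seed_sites("AAANAAA", seed) == 0

    def test_matches_naive_scan_on_random_sequences(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, size=200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            seed = MirnaSeed("m", "".join(rng.choice(bases[:4], size=int(rng.integers(6, 9)))))
            assert count_seed_sites(seq, seed) == naive_site_scan(seq, seed.site)


class TestBsMatrix:
    def _seqset(self, seeds, counts):
        # one gene with planted counts per seed, sites separated by T runs
        parts = []
        for seed, n in zip(seeds, counts):
            parts += [seed.site] * n
        seq = ("TT".join(parts)).ljust(80, "T")
        return select_sequences([rec("G1", seq)])

    def test_planted_counts(self):
        s1 = MirnaSeed("m1", "ACGGCAT")
        s2 = MirnaSeed("m2", "CCGGTAC")
        seqs = self._seqset([s1, s2], [1, 3])
        bs = build_bs_matrix(seqs, [s1, s2], "utr3")
        assert bs.values.to_numpy().tolist() == [[1], [3]]

    def test_zero_mirnas_gives_zero_row_matrix(self):
        seqs = select_sequences([rec("G1", "A" * 60)])
        bs = build_bs_matrix(seqs, [], "utr3")
        assert bs.values.shape == (0, 1)

    def test_identical_seeds_give_identical_rows(self):
        s1 = MirnaSeed("m1", "ACGGCAT")
        s2 = MirnaSeed("m2", "ACGGCAT")
        seqs = self._seqset([s1], [2])
        bs = build_bs_matrix(seqs, [s1, s2], "utr3")
        assert (bs.values.loc["m1"] == bs.values.loc["m2"]).all()

    def test_rows_permutation_equivariant(self, rng):
        seeds = [MirnaSeed(f"m{i}", "".join(rng.choice(list("ACGT"), size=7)))
                 for i in range(5)]
        seqs = select_sequences(
            [rec(f"G{j}", "".join(rng.choice(list("ACGT"), size=150))) for j in range(4)]
        )
        bs = build_bs_matrix(seqs, seeds, "utr3")
        rev = build_bs_matrix(seqs, seeds[::-1], "utr3")
        assert (bs.values.loc[rev.values.index] == rev.values).all().all()

    def test_matches_naive_oracle_cell_exactly(self, rng):
        bases = list("ACGT")
        seeds = [MirnaSeed(f"m{i}", "".join(rng.choice(bases, size=int(rng.integers(6, 9)))))
                 for i in range(6)]
        seqs = select_sequences(
            [rec(f"G{j}", "".join(rng.choice(bases, size=int(rng.integers(60, 300)))))
             for j in range(5)]
        )
        bs = build_bs_matrix(seqs, seeds, "utr3")
        for s in seeds:
            for g in bs.gene_ids:
                assert bs.values.loc[s.mirna_id, g] == naive_site_scan(
                    seqs.get(g, "utr3").sequence, s.site)

    def test_missing_gene_column_omitted(self, caplog):
        seqs = select_sequences([rec("G1", "A" * 60)])
        with caplog.at_level("WARNING"):
            bs = build_bs_matrix(seqs, [MirnaSeed("m", "TTTTTTT")], "utr3",
                                 genes=["G1", "G2"])
        assert bs.gene_ids == ["G1"]
        assert "G2" in caplog.text


class TestDensityMatrix:
    def test_direct_division(self):
        seqs = select_sequences([rec("G1", "A" * 100)])
        bs = build_bs_matrix(seqs, [MirnaSeed("m", "TTTTTTT")], "utr3")
        assert bs.values.iloc[0, 0] == 94  # overlapping poly-A starts
        d = density_matrix(bs, seqs.lengths("utr3"))
        assert d.values.iloc[0, 0] == pytest.approx(0.94)
        assert d.mode == "density"

    def test_reconstructs_counts(self, rng):
        seeds = [MirnaSeed(f"m{i}", "".join(rng.choice(list("ACGT"), size=7)))
                 for i in range(4)]
        seqs = select_sequences(
            [rec(f"G{j}", "".join(rng.choice(list("ACGT"), size=200))) for j in range(6)]
        )
        bs = build_bs_matrix(seqs, seeds, "utr3")
        d = density_matrix(bs, seqs.lengths("utr3"))
        recon = d.values * seqs.lengths("utr3")
        assert np.allclose(recon, bs.values, rtol=1e-12, atol=0)

    def test_zero_length_guarded(self):
        bs = BindingSiteMatrix(
            values=pd.DataFrame([[1]], index=["m"], columns=["G"]),
            region="utr3", mode="count")
        with pytest.raises(ValueError, match="non-positive length"):
            density_matrix(bs, {"G": 0})


class TestIO:
    def test_bs_matrix_round_trip(self, tmp_path, rng):
        values = pd.DataFrame(rng.integers(0, 5, (3, 4)).astype(float),
                              index=pd.Index([f"m{i}" for i in range(3)], name="mirna_id"),
                              columns=[f"G{j}" for j in range(4)])
        bs = BindingSiteMatrix(values=values, region="cds", mode="count")
        bs.to_tsv(tmp_path / "bs.tsv")
        back = BindingSiteMatrix.read_tsv(tmp_path / "bs.tsv")
        assert back.region == "cds" and back.mode == "count"
        assert (back.values == bs.values).all().all()

    def test_fasta_round_trip_and_seed_tsv(self, tmp_path):
        write_fasta({"G1": "ACGT" * 30, "G2": "GGGG" * 20}, tmp_path / "x.fa")
        recs = read_region_fasta(tmp_path / "x.fa", "utr3")
        assert {r.gene_id: r.sequence for r in recs} == {
            "G1": "ACGT" * 30, "G2": "GGGG" * 20}
        (tmp_path / "seeds.tsv").write_text("mirna_id\tseed\nmiR-1\tACGUACG\n")
        seeds = read_seeds(tmp_path / "seeds.tsv")
        assert seeds[0].mirna_id == "miR-1" and seeds[0].seed == "ACGTACG"

    def test_seed_fasta_mature_extraction(self, tmp_path):
        (tmp_path / "m.fa").write_text(">miR-9\nUAGCUUAUCAGACUGAUGUUGA\n")
        seeds = read_seeds(tmp_path / "m.fa", kind="7mer-m8")
        assert seeds[0].seed == "AGCTTAT"
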