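"""Gene identifier grammar, homoeolog pairing, census, and protein similarity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import duplipath as dp
from duplipath.catalog import (
    AMINO_ACIDS,
    CatalogError,
    GeneIdError,
    GeneRecord,
    _pair_by_similarity,
    read_protein_fasta,
)


class TestParseGeneId:
    @pytest.mark.parametrize(
        "raw, subgenome, chrom, locus",
        [
            ("Gohir.A09G161200", "At", 9, 161200),
            ("Gohir.D12G235450", "Dt", 12, 235450),
            ("Gohir.A09G192401", "At", 9, 192401),
            ("Gohir.D02G190400", "Dt", 2, 190400),
        ],
    )
    def test_parses_real_identifiers(self, raw, subgenome, chrom, locus):
        ident = dp.parse_gene_id(raw)
        assert ident.subgenome == subgenome
        assert ident.chromosome == chrom
        assert ident.locus_number == locus

    @pytest.mark.parametrize(
        "raw",
        ["AT1G01010", "", "Gohir.X01G000100", "Gohir.A14G000100", "Gohir.A00G000100",
         "Gohir.A1G000100", "gohir.A01G000100", "Gohir.A01G00010"],
    )
    def test_rejects_malformed(self, raw):
        with pytest.raises(GeneIdError):
            dp.parse_gene_id(raw)

    @given(
        sub=st.sampled_from("AD"),
        chrom=st.integers(1, 13),
        locus=st.integers(0, 999999),
        suffix=st.one_of(st.none(), st.integers(0, 99)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip(self, sub, chrom, locus, suffix):
        raw = f"Gohir.{sub}{chrom:02d}G{locus:06d}" + ("" if suffix is None else str(suffix))
        assert dp.format_gene_id(dp.parse_gene_id(raw)) == raw


def _toy_catalog():
    records = [
        GeneRecord("Gohir.A01G010000", "L1", "GST", "Tau", "Gohir.D01G010000", 900, 3),
        GeneRecord("Gohir.D01G010000", "L1", "GST", "Tau", "Gohir.A01G010000", 900, 3),
        GeneRecord("Gohir.A02G020000", "L2", "GPX", "", None, 600, 2),
        GeneRecord("Gohir.D03G030000", "L3", "GR", "", None, 1200, 5),
    ]
    return dp.GeneCatalog(records)


class TestPairing:
    def test_partner_annotations_pair_once(self):
        pairs, at_only, dt_only = dp.pair_homoeologs(_toy_catalog())
        assert pairs == [("Gohir.A01G010000", "Gohir.D01G010000")]
        assert at_only == ["Gohir.A02G020000"]
        assert dt_only == ["Gohir.D03G030000"]

    def test_real_pair_from_annotations(self):
        records = [
            GeneRecord("Gohir.A09G192401", "Lx", "GST", "Tau", "Gohir.D09G186600", 700, 2),
            GeneRecord("Gohir.D09G186600", "Lx", "GST", "Tau", "Gohir.A09G192401", 700, 2),
        ]
        pairs, _, _ = dp.pair_homoeologs(dp.GeneCatalog(records))
        assert pairs == [("Gohir.A09G192401", "Gohir.D09G186600")]

    def test_same_subgenome_partner_rejected(self):
        records = [
            GeneRecord("Gohir.A01G010000", "L1", "GST", "", "Gohir.A01G020000", 900, 3),
            GeneRecord("Gohir.A01G020000", "L1", "GST", "", "Gohir.A01G010000", 900, 3),
        ]
        with pytest.raises(CatalogError):
            dp.pair_homoeologs(dp.GeneCatalog(records))

    def test_similarity_fallback_tie_broken_by_lowest_locus(self):
        # one At gene, two identical Dt candidates: brute force over both
        # candidate pairings says the scores tie, so the lower locus wins
        records = [
            GeneRecord("Gohir.A05G010000", "La", "GST", "", None, 300, 1),
            GeneRecord("Gohir.D05G020000", "Lb", "GST", "", None, 300, 1),
            GeneRecord("Gohir.D05G010000", "Lc", "GST", "", None, 300, 1),
        ]
        seqs = {
            "Gohir.A05G010000": "ACDEFGHIKL",
            "Gohir.D05G020000": "ACDEFGHIKV",
            "Gohir.D05G010000": "ACDEFGHIKV",
        }
        scores = {
            d: dp.pairwise_similarity(seqs["Gohir.A05G010000"], seqs[d]).percent_identity
            for d in ("Gohir.D05G020000", "Gohir.D05G010000")
        }
        assert scores["Gohir.D05G020000"] == scores["Gohir.D05G010000"]
        pairs, _, dt_only = dp.pair_homoeologs(dp.GeneCatalog(records), sequences=seqs)
        assert pairs == [("Gohir.A05G010000", "Gohir.D05G010000")]
        assert dt_only == ["Gohir.D05G020000"]


class TestLocusSummary:
    def test_printed_census_composition(self):
        cfg = dp.SimulationConfig(seed=0)
        summary = dp.summarize_loci(dp.generate_catalog(cfg))
        assert (summary.n_dual, summary.n_at_only, summary.n_dt_only) == (80, 18, 27)
        assert summary.n_loci == 125
        assert summary.n_genes == 205

    def test_empty_catalog(self):
        s = dp.summarize_loci(dp.GeneCatalog([]))
        assert (s.n_dual, s.n_at_only, s.n_dt_only, s.n_loci, s.n_genes) == (0, 0, 0, 0, 0)

    def test_single_dual_pair(self):
        records = [
            GeneRecord("Gohir.A01G010000", "L1", "GST", "", "Gohir.D01G010000", 900, 3),
            GeneRecord("Gohir.D01G010000", "L1", "GST", "", "Gohir.A01G010000", 900, 3),
        ]
        s = dp.summarize_loci(dp.GeneCatalog(records))
        assert (s.n_dual, s.n_at_only, s.n_dt_only, s.n_loci, s.n_genes) == (1, 0, 0, 1, 2)


class TestFamilyCensus:
    def test_gst_subfamily_arithmetic(self):
        # the GST-domain family tree: 8 canonical subfamilies plus MGST
        subfamily_genes = {
            "Tau": 70, "Phi": 15, "Theta": 10, "Lambda": 7,
            "DHAR": 6, "Zeta": 4, "EF1Bgamma": 3, "TCHQD": 2, "MGST": 4,
        }
        records = []
        i = 0
        for sub, n in subfamily_genes.items():
            for _ in range(n):
                chrom = (i % 13) + 1
                gid = f"Gohir.A{chrom:02d}G{100000 + i * 100:06d}"
                records.append(GeneRecord(gid, f"L{i}", "GST", sub, None, 500, 2))
                i += 1
        census = dp.family_census(dp.GeneCatalog(records), by_subfamily=True)
        assert census["n_genes"].sum() == 121
        assert dict(zip(census["subfamily"], census["n_genes"]))["Tau"] == 70

    def test_census_conserves_totals(self, catalog):
        census = dp.family_census(catalog)
        summary = dp.summarize_loci(catalog)
        assert census["n_genes"].sum() == len(catalog) == summary.n_genes
        assert census["n_loci"].sum() == summary.n_loci

    def test_single_family(self):
        records = [GeneRecord("Gohir.A01G010000", "L1", "GR", "", None, 900, 3)]
        census = dp.family_census(dp.GeneCatalog(records))
        assert len(census) == 1 and census["family"].iloc[0] == "GR"


def _oracle_global_align(a: str, b: str, sub, gap_open=10.0, gap_extend=0.5):
    """Exhaustive enumeration of all global alignments of two short sequences.

    Returns (best identity %, alignment length) among maximum-score
    alignments, scoring gaps affinely per contiguous run.
    """
    best = None

    def walk(i, j, cols):
        nonlocal best
        if i == len(a) and j == len(b):
            score = 0.0
            run = None
            for x, y in cols:
                if x == "-" or y == "-":
                    which = 0 if x == "-" else 1
                    score -= gap_extend if run == which else gap_open + gap_extend
                    run = which
                else:
                    score += sub[x, y]
                    run = None
            n_ident = sum(1 for x, y in cols if x == y)
            ident = 100.0 * n_ident / len(cols)
            key = (score, ident)
            if best is None or score > best[0] or (score == best[0] and ident > best[1]):
                best = (score, ident, len(cols))
            return
        if i < len(a):
            walk(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            walk(i, j + 1, cols + [("-", b[j])])
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols + [(a[i], b[j])])

    walk(0, 0, [])
    return best[1], best[2]


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        res = dp.pairwise_similarity("ACDEFG", "ACDEFG")
        assert res.percent_identity == 100.0
        assert res.percent_similarity == 100.0

    @pytest.mark.parametrize("a, b", [("ACDE", "ACDF"), ("A", "AAAA"), ("WGCN", "WGN"), ("KR", "RK")])
    def test_matches_exhaustive_enumeration_oracle(self, a, b):
        from Bio.Align import substitution_matrices

        sub = substitution_matrices.load("BLOSUM62")
        oracle_ident, oracle_len = _oracle_global_align(a, b, sub)
        res = dp.pairwise_similarity(a, b)
        assert res.alignment_length == oracle_len
        assert res.percent_identity == pytest.approx(oracle_ident)

    def test_known_values(self):
        assert dp.pairwise_similarity("ACDE", "ACDF").percent_identity == 75.0
        res = dp.pairwise_similarity("A", "AAAA")
        assert res.alignment_length == 4
        assert res.percent_identity == 25.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            dp.pairwise_similarity("AC1E", "ACDE")
        with pytest.raises(ValueError):
            dp.pairwise_similarity("", "ACDE")

    def test_identity_bounded_by_similarity(self):
        rng = np.random.default_rng(0)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(alphabet, size=rng.integers(5, 15)))
            b = "".join(rng.choice(alphabet, size=rng.integers(5, 15)))
            res = dp.pairwise_similarity(a, b)
            assert 0 <= res.percent_identity <= res.percent_similarity <= 100


class TestSimilarityMatrix:
    def test_symmetry_diagonal_and_entrywise_match(self):
        rng = np.random.default_rng(1)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = {
            f"g{i}": "".join(rng.choice(alphabet, size=12)) for i in range(5)
        }
        ident, simil = dp.similarity_matrix(seqs)
        assert np.allclose(ident.to_numpy(), ident.to_numpy().T)
        assert np.allclose(np.diag(ident.to_numpy()), 100.0)
        for i, j in itertools.combinations(seqs, 2):
            res = dp.pairwise_similarity(seqs[i], seqs[j])
            assert ident.loc[i, j] == pytest.approx(res.percent_identity)
            assert simil.loc[i, j] == pytest.approx(res.percent_similarity)

    def test_identical_pair_and_too_few(self):
        ident, _ = dp.similarity_matrix({"a": "ACDE", "b": "ACDE"})
        assert ident.loc["a", "b"] == 100.0
        with pytest.raises(ValueError):
            dp.similarity_matrix({"a": "ACDE"})


def test_catalog_tsv_round_trip(tmp_path, catalog):
    path = tmp_path / "catalog.tsv"
    catalog.to_tsv(path)
    back = dp.GeneCatalog.from_tsv(path)
    assert back.to_frame().equals(catalog.to_frame())


def test_protein_fasta_reader(tmp_path):
    path = tmp_path / "prot.fa"
    path.write_text(">g1\nACDE\n>g2\nWGCN\n")
    assert read_protein_fasta(path) == {"g1": "ACDE", "g2": "WGCN"}
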