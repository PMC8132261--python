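"""Parsing, validation and allele harmonization of summary-statistics tables."""
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from covcoloc.errors import ConfigError, InputError, NoOverlapError
from covcoloc.sumstats import (AssocTable, StudyMeta, VariantKey,
                               harmonize_pair, parse_eqtl_associations,
                               parse_gwas_sumstats, parse_variant_id,
                               read_assoc_table, write_assoc_table)
from conftest import make_table


class TestVariantKey:
    def test_total_ordering_follows_canonical_chromosomes(self):
        keys = [VariantKey("X", 5, "A", "G"), VariantKey("2", 9, "A", "G"),
                VariantKey("10", 1, "A", "G"), VariantKey("2", 9, "A", "C")]
        ordered = sorted(keys)
        assert [k.chrom for k in ordered] == ["2", "2", "10", "X"]
        assert ordered[0].alt == "C"  # alt breaks the tie at 2:9

    @pytest.mark.parametrize("pos,ref,alt", [(0, "A", "G"), (5, "A", "A"),
                                             (5, "", "G")])
    def test_invalid_keys_rejected(self, pos, ref, alt):
        with pytest.raises(ValueError):
            VariantKey("1", pos, ref, alt)


class TestParseGwas:
    def test_identity_parse_sorted_by_position(self, toy_gwas_tsv, meta_a):
        t = parse_gwas_sumstats(toy_gwas_tsv, meta_a)
        assert len(t) == 3 and t.n_dropped == 0
        assert list(t.df["pos"]) == [55, 101, 200]
        # per-variant n falls back to the study total
        assert (t.df["n"] == 100_000).all()

    def test_p_zero_row_dropped_and_counted(self, meta_a):
        text = ("#CHR\tPOS\tREF\tALT\tall_inv_var_meta_p\n"
                "1\t100\tA\tG\t0.0\n1\t200\tA\tG\t0.5\n")
        t = parse_gwas_sumstats(io.StringIO(text), meta_a)
        assert len(t) == 1 and t.n_dropped == 1

    def test_duplicate_variant_keeps_smaller_p(self, meta_a):
        text = ("#CHR\tPOS\tREF\tALT\tall_inv_var_meta_p\n"
                "1\t100\tA\tG\t1e-3\n1\t100\tA\tG\t1e-8\n")
        t = parse_gwas_sumstats(io.StringIO(text), meta_a)
        assert len(t) == 1
        assert t.df["p"].iloc[0] == pytest.approx(1e-8)

    def test_missing_mandatory_column_names_it(self, meta_a):
        text = "#CHR\tPOS\tREF\tall_inv_var_meta_p\n1\t100\tA\t0.5\n"
        with pytest.raises(ConfigError, match="alt"):
            parse_gwas_sumstats(io.StringIO(text), meta_a)

    def test_empty_after_filtering_is_an_error(self, meta_a):
        text = "#CHR\tPOS\tREF\tALT\tall_inv_var_meta_p\n1\t100\tA\tG\t2.0\n"
        with pytest.raises(InputError):
            parse_gwas_sumstats(io.StringIO(text), meta_a)


class TestParseEqtl:
    GTEX = ("gene_id\tvariant_id\ttss_distance\tma_samples\tma_count\tmaf"
            "\tpval_nominal\tslope\tslope_se\n")

    def test_variant_id_format(self):
        k = parse_variant_id("3_101000000_A_G_b37")
        assert (k.chrom, k.pos, k.ref, k.alt) == ("3", 101000000, "A", "G")

    def test_two_genes_give_two_tables(self):
        rows = [f"ENSG{g}\t1_{100+i}_A_G_b37\t0\t10\t10\t0.2\t0.5\t0.1\t0.2"
                for g in ("01", "02") for i in range(5)]
        out = parse_eqtl_associations(io.StringIO(self.GTEX + "\n".join(rows)),
                                      tissue="Lung", n=300)
        assert len(out) == 2
        assert all(len(t) == 5 for _, t in out)
        assert all(d.tissue == "Lung" and d.n == 300 for d, _ in out)

    def test_major_allele_maf_stored_verbatim(self):
        # eaf column holds the file's frequency as-is; no silent folding
        row = "ENSG01\t1_100_A_G_b37\t0\t10\t10\t0.62\t0.5\t0.1\t0.2\n"
        out = parse_eqtl_associations(io.StringIO(self.GTEX + row), "Lung", 300)
        (_, table), = out
        assert table.df["eaf"].iloc[0] == pytest.approx(0.62)

    def test_unparseable_variant_dropped_with_count(self):
        rows = ("ENSG01\tgarbage\t0\t10\t10\t0.2\t0.5\t0.1\t0.2\n"
                "ENSG01\t1_100_A_G_b37\t0\t10\t10\t0.2\t0.5\t0.1\t0.2\n")
        (_, table), = parse_eqtl_associations(
            io.StringIO(self.GTEX + rows), "Lung", 300)
        assert len(table) == 1 and table.n_dropped == 1


class TestHarmonize:
    def rows(self):
        return [("1", 100, "A", "G", 0.1, 0.1, 0.32, 0.3),
                ("1", 200, "C", "T", 0.2, 0.1, 0.046, 0.4),
                ("1", 300, "A", "C", -0.1, 0.1, 0.32, 0.2),
                ("1", 400, "G", "T", 0.0, 0.1, 1.0, 0.5)]

    def test_identical_tables_pair_without_flips(self, meta_a, meta_b):
        a = make_table(meta_a, self.rows())
        b = make_table(meta_b, self.rows())
        pair = harmonize_pair(a, b)
        assert len(pair) == 4 and pair.n_flipped == 0 and pair.n_dropped == 0
        assert np.allclose(pair.df["beta_a"], pair.df["beta_b"])

    def test_swapped_alleles_flip_beta_and_complement_eaf(self, meta_a, meta_b):
        a = make_table(meta_a, [("1", 200, "C", "T", 0.1, 0.1, 0.32, 0.4)])
        b = make_table(meta_b, [("1", 200, "T", "C", 0.2, 0.1, 0.046, 0.3)])
        pair = harmonize_pair(a, b)
        assert pair.n_flipped == 1
        assert pair.df["beta_b"].iloc[0] == pytest.approx(-0.2)
        assert pair.df["eaf_b"].iloc[0] == pytest.approx(0.7)

    def test_strand_ambiguous_swap_dropped(self, meta_a, meta_b):
        # A/T pair with swapped labels cannot be distinguished from a strand
        # flip; conservative rule drops it
        a = make_table(meta_a, [("1", 100, "A", "T", 0.1, 0.1, 0.32, 0.3),
                                ("1", 200, "C", "T", 0.1, 0.1, 0.32, 0.3)])
        b = make_table(meta_b, [("1", 100, "T", "A", 0.1, 0.1, 0.32, 0.3),
                                ("1", 200, "C", "T", 0.1, 0.1, 0.32, 0.3)])
        pair = harmonize_pair(a, b)
        assert len(pair) == 1 and pair.n_dropped == 1

    def test_partial_overlap_intersects(self, meta_a, meta_b):
        a = make_table(meta_a, self.rows() + [("1", 500, "A", "G", 0, 0.1, 1, 0.5)])
        b = make_table(meta_b, self.rows()[:3] +
                       [("1", 900, "A", "G", 0, 0.1, 1, 0.5),
                        ("1", 950, "A", "G", 0, 0.1, 1, 0.5)])
        pair = harmonize_pair(a, b)
        assert len(pair) == 3

    def test_no_overlap_raises_with_study_names(self, meta_a, meta_b):
        a = make_table(meta_a, [("1", 100, "A", "G", 0, 0.1, 1, 0.5)])
        b = make_table(meta_b, [("2", 100, "A", "G", 0, 0.1, 1, 0.5)])
        with pytest.raises(NoOverlapError, match="C2_eur_with_ukbb"):
            harmonize_pair(a, b)

    def test_symmetry_of_shared_set_and_self_harmonization(self, meta_a, meta_b):
        a = make_table(meta_a, self.rows())
        b = make_table(meta_b, self.rows()[:2])
        ab, ba = harmonize_pair(a, b), harmonize_pair(b, a)
        assert set(map(str, ab.variants)) == set(map(str, ba.variants))
        aa = harmonize_pair(a, a)
        assert len(aa) == len(a) and aa.n_flipped == 0 and aa.n_dropped == 0


@settings(max_examples=25, deadline=None)
@given(st.lists(
    st.tuples(st.integers(1, 22), st.integers(1, 10_000),
              st.sampled_from(["A", "C"]), st.sampled_from(["G", "T"]),
              st.floats(-1, 1), st.floats(0.01, 1),
              st.floats(1e-10, 1.0, exclude_min=False),
              st.floats(0.01, 0.99)),
    min_size=1, max_size=30,
    unique_by=lambda r: (r[0], r[1], r[2], r[3])))
def test_write_read_round_trip_preserves_table(tmp_path_factory, rows):
    """Writing a table and parsing it back reproduces fields and order."""
    meta = StudyMeta(study_id="A2_eur_with_ukbb", phenotype="A2",
                     ancestry="eur", controls="with_ukbb", n_total=1000,
                     n_cases=100)
    table = make_table(meta, [(str(c), p, r, a, b, s, pv, f)
                              for c, p, r, a, b, s, pv, f in rows])
    path = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_assoc_table(table, path)
    back = read_assoc_table(path, meta)
    pd.testing.assert_frame_equal(table.df, back.df)
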