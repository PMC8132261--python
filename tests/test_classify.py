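"""Locus taxonomy rules and the within/between phenotype comparison."""
import itertools

import numpy as np
import pytest

from covcoloc.classify import (PPMatrix, classify_from_phenotype_maxima,
                               classify_locus, pairwise_pp_matrix,
                               phenotype_maxima,
                               within_between_phenotype_comparison)
from covcoloc.errors import InputError
from covcoloc.loci import Locus
from covcoloc.simulate import LDSpec, ar_correlation, simulate_study
from covcoloc.sumstats import default_study_panel


def make_ppm(panel, pph4_pairs=(), pph3_pairs=(), sig=(), default=0.01):
    """Build a PPMatrix with given (study_id_a, study_id_b, value) entries."""
    ids = [s.study_id for s in panel]
    k = len(ids)
    pph4 = np.full((k, k), float(default))
    pph3 = np.full((k, k), float(default))
    np.fill_diagonal(pph4, np.nan)
    np.fill_diagonal(pph3, np.nan)
    for a, b, v in pph4_pairs:
        i, j = ids.index(a), ids.index(b)
        pph4[i, j] = pph4[j, i] = v
    for a, b, v in pph3_pairs:
        i, j = ids.index(a), ids.index(b)
        pph3[i, j] = pph3[j, i] = v
    sig_arr = np.array([s in sig for s in ids])
    return PPMatrix(Locus("1", 1, 2_000_000), list(panel), pph4, pph3, sig_arr)


C2 = ["C2_eur_with_ukbb", "C2_eur_without_ukbb",
      "C2_multi_with_ukbb", "C2_multi_without_ukbb"]
B2 = ["B2_eur_with_ukbb", "B2_eur_without_ukbb",
      "B2_multi_with_ukbb", "B2_multi_without_ukbb"]
A2 = ["A2_eur_with_ukbb", "A2_eur_without_ukbb",
      "A2_multi_with_ukbb", "A2_multi_without_ukbb"]
B1 = ["B1_eur_with_ukbb", "B1_eur_without_ukbb",
      "B1_multi_with_ukbb", "B1_multi_without_ukbb"]


class TestClassifyLocus:
    def test_c2_colocalization_dominates_severity_phenotypes(self, panel):
        # all four phenotypes colocalize internally; C2 rule wins
        pairs = [(a, b, 0.998) for ph in (C2, A2, B2)
                 for a, b in itertools.combinations(ph, 2)]
        ann = classify_locus(make_ppm(panel, pairs, sig=C2 + A2 + B2))
        assert ann.susceptibility is True
        assert ann.severity is False
        assert any(q == "PP-H4" for _, _, q, _ in ann.evidence)

    def test_severity_without_c2_colocalization(self, panel):
        pairs = [(B1[0], B1[1], 0.973)]
        ann = classify_locus(make_ppm(panel, pairs, sig=B1[:2]))
        assert ann.susceptibility is False
        assert ann.severity is True

    def test_all_below_threshold_gives_no_flags(self, panel):
        ann = classify_locus(make_ppm(panel, default=0.3))
        assert (ann.susceptibility, ann.severity, ann.ethnicity_specific,
                ann.two_signals) == (False, False, False, False)

    def test_two_signals_requires_both_members_significant(self, panel):
        pairs_h4 = [(C2[0], C2[1], 0.99)]
        pairs_h3 = [(C2[0], B1[0], 0.81)]
        # H3 partner not significant -> no two-signal call
        ann = classify_locus(make_ppm(panel, pairs_h4, pairs_h3, sig=C2))
        assert ann.two_signals is False
        # both members significant -> flagged
        ann2 = classify_locus(make_ppm(panel, pairs_h4, pairs_h3,
                                       sig=C2 + [B1[0]]))
        assert ann2.two_signals is True

    def test_ethnicity_specific_needs_cross_ancestry_failure(self, panel):
        within = [("B2_multi_with_ukbb", "B2_multi_without_ukbb", 0.996)]
        ann = classify_locus(make_ppm(panel, within,
                                      sig=["B2_multi_with_ukbb",
                                           "B2_multi_without_ukbb"]))
        assert ann.ethnicity_specific is True
        # a colocalizing cross-ancestry pair suppresses the flag
        cross = within + [("B2_eur_with_ukbb", "B2_multi_with_ukbb", 0.95)]
        ann2 = classify_locus(make_ppm(panel, cross,
                                       sig=["B2_multi_with_ukbb",
                                            "B2_multi_without_ukbb",
                                            "B2_eur_with_ukbb"]))
        assert ann2.ethnicity_specific is False

    def test_single_ancestry_significance_path(self, panel):
        # only one European study significant, no within-ancestry pair
        # colocalizes, cross-ancestry pairs all low
        ann = classify_locus(make_ppm(panel, sig=["C2_eur_with_ukbb"],
                                      default=0.01))
        assert ann.ethnicity_specific is True

    def test_invariant_to_study_ordering(self, panel):
        pairs = [(C2[0], C2[2], 0.95), (B1[0], B1[1], 0.92)]
        m1 = make_ppm(panel, pairs, sig=C2)
        perm = list(reversed(panel))
        m2 = make_ppm(perm, pairs, sig=C2)
        a1, a2 = classify_locus(m1), classify_locus(m2)
        assert (a1.susceptibility, a1.severity, a1.two_signals) == \
            (a2.susceptibility, a2.severity, a2.two_signals)

    def test_partial_panel_reports_not_evaluable(self, panel):
        # two B2 studies only: susceptibility undecidable, severity too
        sub = [s for s in panel if s.study_id in B2[:2]]
        ann = classify_locus(make_ppm(sub, [(B2[0], B2[1], 0.99)], sig=B2[:2]))
        assert ann.susceptibility is None
        assert ann.severity is None

    def test_all_missing_matrix_gives_all_false_flags(self, panel):
        m = make_ppm(panel, default=np.nan)
        ann = classify_locus(m)
        assert ann.category == "Unassigned"

    def test_category_vocabulary(self, panel):
        pairs = [(B2[2], B2[3], 0.996)]
        ann = classify_locus(make_ppm(panel, pairs, sig=B2[2:]))
        assert ann.category == "Severity; Ethnicity-specific signal"


class TestReducedClassifier:
    @pytest.mark.parametrize("maxima,expected", [
        ({"A2": 0.057, "B1": 0.005, "B2": 0.985, "C2": 0.057}, "severity"),
        ({"A2": 0.968, "B1": 0.102, "B2": 0.990, "C2": 0.999},
         "susceptibility"),
        ({"A2": 0.5, "B1": 0.5, "B2": 0.5, "C2": 0.5}, "unassigned"),
    ])
    def test_published_maxima_reduce_to_categories(self, maxima, expected):
        assert classify_from_phenotype_maxima(maxima) == expected

    def test_missing_phenotype_is_an_error(self):
        with pytest.raises(InputError):
            classify_from_phenotype_maxima({"A2": 0.9, "B1": 0.9, "B2": 0.9})

    def test_agrees_with_full_classifier_on_plain_loci(self, panel):
        pairs = [(C2[0], C2[1], 0.97)]
        m = make_ppm(panel, pairs, sig=C2[:2])
        ann = classify_locus(m)
        reduced = classify_from_phenotype_maxima(phenotype_maxima(m))
        assert ann.susceptibility and reduced == "susceptibility"


class TestWithinBetweenComparison:
    def _ppm_with_values(self, panel, within_vals, between_vals):
        ids = [s.study_id for s in panel]
        k = len(ids)
        pph4 = np.full((k, k), np.nan)
        wi, bi = iter(within_vals), iter(between_vals)
        for i, j in itertools.combinations(range(k), 2):
            same = panel[i].phenotype == panel[j].phenotype
            try:
                v = next(wi) if same else next(bi)
            except StopIteration:
                continue
            pph4[i, j] = pph4[j, i] = v
        return PPMatrix(None, list(panel), pph4, np.full((k, k), np.nan),
                        np.zeros(k, dtype=bool))

    def test_identical_groups_give_large_p(self, panel):
        vals = [0.1, 0.5, 0.9]
        m = self._ppm_with_values(panel, vals, vals)
        _, _, p = within_between_phenotype_comparison([m])
        assert p > 0.99

    def test_exact_enumeration_small_groups(self, panel):
        m = self._ppm_with_values(panel, [0.9, 0.95, 0.99], [0.1, 0.2, 0.3])
        med_w, med_b, p = within_between_phenotype_comparison([m])
        assert med_w == pytest.approx(0.95)
        assert med_b == pytest.approx(0.2)
        # U = 9 of 9; two-sided exact p over C(6,3) = 20 assignments
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_group_is_an_error(self, panel):
        m = self._ppm_with_values(panel, [0.9], [])
        with pytest.raises(InputError):
            within_between_phenotype_comparison([m])


class TestPairwiseMatrix:
    def _sim_tables(self, panel, causal_per_study, seed=11, q=120):
        spec = LDSpec(block_size=30, rho=0.9)
        R = ar_correlation(q, spec)
        rng = np.random.default_rng(seed)
        mafs = rng.uniform(0.1, 0.5, size=q)
        return [simulate_study(R, mafs, causal_per_study(s), s,
                               seed=np.random.default_rng(rng.integers(2**31)))
                for s in panel]

    def test_shared_causal_panel_colocalizes_everywhere(self, panel):
        sub = panel[:4]
        tables = self._sim_tables(sub, lambda s: {60: 8.0})
        m = pairwise_pp_matrix(Locus("1", 1, 2_000_000), tables)
        iu = np.triu_indices(4, 1)
        assert np.all(m.pph4[iu] > 0.9)

    def test_signal_vs_null_study_puts_mass_on_single_trait(self, panel):
        sub = panel[:2]
        tables = self._sim_tables(
            sub, lambda s: {60: 8.0} if s.study_id == sub[0].study_id else None)
        m = pairwise_pp_matrix(Locus("1", 1, 2_000_000), tables)
        res = m.results[(0, 1)]
        assert res["H1"] > 0.5
        assert res["H4"] < 0.1
        assert m.sig[0] and not m.sig[1]
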