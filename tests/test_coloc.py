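"""Colocalization engine: log-ABFs, posterior algebra, oracle agreement."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covcoloc.coloc import (Priors, coloc_abf, coloc_oracle_enumeration,
                            coloc_pair, is_colocalized, labf_from_beta,
                            labf_from_p, z_from_p)
from covcoloc.errors import ConfigError, InputError, NoOverlapError
from covcoloc.sumstats import harmonize_pair
from conftest import make_table


class TestLabfFromBeta:
    def test_zero_prior_variance_means_no_evidence(self):
        assert labf_from_beta(0.0, 1.0, 0.0) == 0.0

    def test_frozen_arithmetic_oracles(self):
        # z = 3, V = 0.01, W = 0.04 -> r = 0.8, lABF = 0.5(ln 0.2 + 9*0.8)
        assert labf_from_beta(0.3, 0.1, 0.2) == \
            pytest.approx(2.7952810437829498, rel=1e-12)
        # null z: lABF = 0.5 ln(1/1.04)
        assert labf_from_beta(0.0, 1.0, 0.2) == \
            pytest.approx(-0.019610356576640648, rel=1e-12)

    def test_strictly_increasing_in_abs_z(self):
        zs = np.linspace(0, 10, 40)
        vals = labf_from_beta(zs * 0.1, 0.1, 0.2)
        assert np.all(np.diff(vals) > 0)

    def test_invalid_se_rejected(self):
        with pytest.raises(InputError):
            labf_from_beta(0.1, 0.0, 0.2)


class TestLabfFromP:
    def test_null_p_gives_negative_labf(self):
        v = labf_from_p(1.0, 0.3, 10_000, "quantitative", prior_sd=0.15)
        assert v < 0

    def test_symmetric_in_allele_frequency_folding(self):
        a = labf_from_p(1e-5, 0.3, 10_000, "quantitative", prior_sd=0.15)
        b = labf_from_p(1e-5, 0.7, 10_000, "quantitative", prior_sd=0.15)
        assert a == pytest.approx(b, rel=1e-14)

    def test_frozen_high_precision_oracle(self):
        v = labf_from_p(1e-8, 0.3, 10_000, "quantitative", prior_sd=0.15)
        assert v == pytest.approx(13.969119821999465, rel=1e-10)

    def test_tiny_p_stays_finite_via_log_quantile_path(self):
        z = z_from_p(5e-324)
        assert np.isfinite(z) and z > 38
        v = labf_from_p(5e-324, 0.3, 10_000, "case_control", case_fraction=0.1)
        assert np.isfinite(v)

    def test_case_control_requires_case_fraction(self):
        with pytest.raises(ConfigError):
            labf_from_p(0.5, 0.3, 10_000, "case_control")


class TestColocAbf:
    def test_single_null_variant_posteriors_follow_priors(self):
        res = coloc_abf([0.0], [0.0])
        # pp proportional to (1, p1, p2, 0, p12)
        assert res.pp[0] == pytest.approx(0.9997900440907409, abs=1e-12)
        assert res["H3"] == 0.0
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ten_null_variants_combinatorial_weights(self):
        res = coloc_oracle_enumeration([0.0] * 10, [0.0] * 10)
        p1 = p2 = 1e-4
        p12 = 1e-5
        w = np.array([1.0, 10 * p1, 10 * p2, 90 * p1 * p2, 10 * p12])
        assert np.allclose(res.pp, w / w.sum(), atol=1e-12)

    def test_shared_strong_signal_gives_h4(self):
        res = coloc_abf([20.0, 0.0], [20.0, 0.0])
        assert res["H4"] > 0.99

    def test_distinct_strong_signals_give_h3(self):
        res = coloc_abf([20.0, 0.0], [0.0, 20.0])
        assert res["H3"] > 0.9

    def test_snp_posterior_is_softmax_of_joint_evidence(self):
        labf1, labf2 = np.array([3.0, 1.0, 0.0]), np.array([2.0, 2.5, 0.0])
        res = coloc_abf(labf1, labf2)
        joint = np.exp(labf1 + labf2)
        assert np.allclose(res.snp_pp_h4, joint / joint.sum(), atol=1e-12)
        assert res.snp_pp_h4.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_overlap_is_an_error(self):
        with pytest.raises(NoOverlapError):
            coloc_abf([], [])

    def test_monotone_shared_evidence_drives_h4_to_one(self):
        prev = 0.0
        for scale in (2.0, 5.0, 10.0, 20.0, 40.0):
            res = coloc_abf([scale, 0.0, 0.0], [scale, 0.0, 0.0])
            assert res["H4"] > prev
            prev = res["H4"]
        assert prev > 0.999

    def test_probability_zero_variant_leaves_posteriors_unchanged(self):
        base = coloc_abf([5.0, 1.0], [4.0, 2.0])
        extended = coloc_abf([5.0, 1.0, -1e308], [4.0, 2.0, -1e308])
        assert np.allclose(base.pp, extended.pp, atol=1e-12)


class TestPriors:
    def test_invalid_priors_rejected(self):
        with pytest.raises(ConfigError):
            Priors(p1=1e-6, p2=1e-4, p12=1e-5)  # p12 > p1
        with pytest.raises(ConfigError):
            Priors(p1=0.5, p2=0.5, p12=0.1)  # sums past 1


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(1, 50), st.integers(0, 2 ** 31 - 1))
def test_engine_normalization_swap_symmetry_and_oracle(q, seed):
    """On random instances: posteriors normalise, swapping traits exchanges
    H1 and H2 while H0/H3/H4 are unchanged, and the log-space engine agrees
    with the direct enumeration oracle."""
    rng = np.random.default_rng(seed)
    labf1 = rng.normal(0, 10, size=q)
    labf2 = rng.normal(0, 10, size=q)
    res = coloc_abf(labf1, labf2)
    assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)
    assert res.snp_pp_h4.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(res.pp >= 0)
    swapped = coloc_abf(labf2, labf1)
    assert swapped["H1"] == pytest.approx(res["H2"], abs=1e-12)
    assert swapped["H2"] == pytest.approx(res["H1"], abs=1e-12)
    for h in ("H0", "H3", "H4"):
        assert swapped[h] == pytest.approx(res[h], abs=1e-12)
    assert np.allclose(swapped.snp_pp_h4, res.snp_pp_h4, atol=1e-12)
    oracle = coloc_oracle_enumeration(labf1, labf2)
    assert np.allclose(res.pp, oracle.pp, atol=1e-10)
    if q == 1:
        assert res["H3"] == 0.0


class TestIsColocalized:
    @pytest.mark.parametrize("pph4,expected", [
        (0.904, True),   # counted as colocalized
        (0.9, False),    # strict boundary
        (0.444, False),
    ])
    def test_strict_threshold(self, pph4, expected):
        pp = np.array([0, 0, 0, 1 - pph4, pph4])
        res = coloc_abf([1.0], [1.0])
        res.pp = pp
        assert is_colocalized(res) is expected


class TestColocPair:
    def rows(self, betas):
        return [("1", 100 + i, "A", "G", b, 0.05, 0.5, 0.3)
                for i, b in enumerate(betas)]

    def test_beta_and_pvalue_modes_agree_on_consistent_stats(self, meta_a,
                                                             meta_b):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 2, size=30)
        se = 0.05
        from scipy.stats import norm
        rows = [("1", 100 + i, "A", "G", z[i] * se, se,
                 float(2 * norm.sf(abs(z[i]))), 0.3) for i in range(30)]
        a = make_table(meta_a, rows)
        b = make_table(meta_b, rows)
        pair = harmonize_pair(a, b)
        res_beta = coloc_pair(pair, mode="beta")
        res_p = coloc_pair(pair, mode="pvalue")
        # p-value mode replaces V by the frequency approximation, so only
        # the qualitative conclusion must agree
        assert abs(res_beta["H4"] - res_p["H4"]) < 0.2

    def test_minimum_overlap_enforced(self, meta_a, meta_b):
        a = make_table(meta_a, self.rows([0.1]))
        b = make_table(meta_b, self.rows([0.1]))
        with pytest.raises(NoOverlapError):
            coloc_pair(harmonize_pair(a, b), min_nsnps=2)
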