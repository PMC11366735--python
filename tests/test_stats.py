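"""Ratio operations and the comparison-statistics battery."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from lesiondx.stats import (
    bonferroni_alpha,
    gradient_profile,
    group_summary,
    ratio,
    tukey_hsd,
    two_proportion_test,
    two_sided_t_test,
)
from lesiondx.schema import Cohort

from conftest import make_patient


class TestRatio:
    def test_identity(self):
        assert ratio(3.7, 3.7) == 1.0

    def test_contralateral_normalization(self):
        assert ratio(890.0, 1000.0) == pytest.approx(0.89)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ratio(1.0, 0.0)


class TestGradientProfile:
    def test_flat_profile_is_unity(self):
        assert gradient_profile([2.0, 2.0, 2.0], 2.0) == {5: 1.0, 10: 1.0, 20: 1.0}

    def test_published_style_profile(self):
        ref = 700.0
        prof = gradient_profile([1.79 * ref, 2.07 * ref, 2.28 * ref], ref)
        assert prof[5] == pytest.approx(1.79)
        assert prof[20] == pytest.approx(2.28)

    def test_absent_distances_are_absent(self):
        prof = gradient_profile([1.9 * 700, None, None], 700.0)
        assert set(prof) == {5}

    def test_all_absent_rejected(self):
        with pytest.raises(ValueError):
            gradient_profile([None, None, None], 700.0)


class TestTTest:
    def test_identical_groups(self):
        res = two_sided_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_small_n(self):
        # pooled s = 1, t = 10 / sqrt(2/3) with df 4 -> p well below 0.01
        res = two_sided_t_test([11.0, 12.0, 13.0], [1.0, 2.0, 3.0],
                               variant="student")
        assert res.p_value < 0.01
        assert res.statistic > 0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 40)
        r1 = two_sided_t_test(a, b)
        r2 = two_sided_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_published_group_parameters_are_significant(self):
        # median p over replicates at the published n/means/SDs
        ps = []
        for r in range(11):
            rng = np.random.default_rng(1000 + r)
            a = rng.normal(1.05, 0.35, 181)
            b = rng.normal(0.89, 0.36, 187)
            ps.append(two_sided_t_test(a, b).p_value)
        assert np.median(ps) < 0.001

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            two_sided_t_test([1.0], [1.0, 2.0])


def _fisher_oracle(k1, n1, k2, n2):
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the observed margins."""
    total_success = k1 + k2
    total = n1 + n2
    rv = sps.hypergeom(total, total_success, n1)
    p_obs = rv.pmf(k1)
    support = range(max(0, total_success - n2), min(n1, total_success) + 1)
    return sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9))


class TestTwoProportion:
    def test_identical_proportions(self):
        assert two_proportion_test(10, 100, 10, 100).p_value == pytest.approx(1.0)
        assert two_proportion_test(1, 2, 1, 2).p_value == pytest.approx(1.0)

    def test_typical_curve_contrast_is_extreme(self):
        # 23/73 lymphoma lesions vs 0/134 glioblastoma lesions
        assert two_proportion_test(23, 73, 0, 134).p_value < 1e-8

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n1, n2 = rng.integers(1, 31, size=2)
            k1 = rng.integers(0, n1 + 1)
            k2 = rng.integers(0, n2 + 1)
            got = two_proportion_test(int(k1), int(n1), int(k2), int(n2)).p_value
            want = _fisher_oracle(int(k1), int(n1), int(k2), int(n2))
            assert got == pytest.approx(want, abs=1e-9), (k1, n1, k2, n2)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(5, 4, 0, 10)


class TestTukey:
    def test_identical_groups_not_significant(self):
        g = list(np.linspace(0, 1, 50))
        res = tukey_hsd({"a": g, "b": g, "c": g})
        assert all(r.p_value > 0.99 for r in res.values())

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0, 2.0], "b": [2.0, 3.0]})

    def test_subgroup_rank_structure(self):
        # four subgroups at the published tumor-ADC parameters and sizes;
        # the lymphoma-vs-multifocal-glioblastoma pair dominates
        rng = np.random.default_rng(7)
        groups = {
            "multifocal_mGB": rng.normal(1.05, 0.34, 153),
            "multicentric_mGB": rng.normal(1.06, 0.41, 28),
            "mPCNSL": rng.normal(0.89, 0.29, 144),
            "mSCNSL": rng.normal(0.90, 0.56, 43),
        }
        res = tukey_hsd(groups)
        best = min(res, key=lambda pair: res[pair].p_value)
        assert set(best) == {"mPCNSL", "multifocal_mGB"}

    def test_adjusted_p_dominates_welch_p(self):
        rng = np.random.default_rng(5)
        wins = trials = 0
        for _ in range(40):
            groups = {
                k: rng.normal(rng.normal(0, 0.3), 1.0, rng.integers(5, 15))
                for k in "abcd"
            }
            adj = tukey_hsd(groups)
            for (k1, k2), res in adj.items():
                raw = two_sided_t_test(groups[k1], groups[k2]).p_value
                trials += 1
                wins += res.p_value >= raw
        assert wins / trials >= 0.95


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 20, 0.0025), (0.05, 1, 0.05), (0.05, 2, 0.025)]
    )
    def test_values(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_inverse_identity(self):
        for m in (1, 3, 7, 20, 100):
            assert math.isclose(bonferroni_alpha(0.05, m) * m, 0.05, rel_tol=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 3)


class TestGroupSummary:
    def test_fixture_solid_proportion(self, fixture_cohort):
        s = group_summary(fixture_cohort, "entity")
        cat = s["mCNSL"].categories["morphology:solid"]
        assert (cat.count, cat.denominator) == (139, 187)

    def test_denominators_follow_modality(self, fixture_cohort):
        s = group_summary(fixture_cohort, "entity")
        tc = s["mCNSL"].categories["typical_curve"]
        assert (tc.count, tc.denominator) == (23, 73)
        pa = s["mCNSL"].categories["perfusion_available"]
        assert (pa.count, pa.denominator) == (17, 50)

    def test_single_observation_sd_absent(self):
        cohort = Cohort([make_patient(n_lesions=2)])
        s = group_summary(cohort, "entity")["mGB"]
        assert s.features["lesions_per_patient"].sd is None

    def test_synthetic_mgb_tumor_adc_recovery(self, large_synthetic_pair):
        gb, _ = large_synthetic_pair
        s = group_summary(gb, "entity")["mGB"]
        assert s.features["adc_ratio_tumor"].mean == pytest.approx(1.05, abs=0.02)

    def test_subtype_stratification(self, fixture_cohort):
        s = group_summary(fixture_cohort, "subtype")
        assert set(s) == {"multifocal", "multicentric", "PCNSL", "SCNSL"}
        assert s["PCNSL"].n_patients == 38
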