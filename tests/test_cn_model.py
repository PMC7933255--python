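import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import branching_pmf_exact
from wgdevolve.cn_model import (ArmCNProfile, BranchingParams, FitResult,
                                copy_number_pmf, fit_model, log_likelihood,
                                max_total_copy_number, offspring_pgf,
                                select_model, summarize_arms)
from wgdevolve.errors import (FitError, ParameterError,
                              UnrepresentableStateError, ValidationError)
from wgdevolve.io_formats import segment_table_from_records
from wgdevolve.synthetic import simulate_arm_counts, simulate_arm_profile


def uniform_profile(state, n_arms=39, sample_id="s"):
    return ArmCNProfile(sample_id=sample_id,
                        arms={f"a{i}": state for i in range(n_arms)})


class TestOffspringPgf:
    @pytest.mark.parametrize("abg", [(0.0, 1.0, 0.0), (0.1, 0.8, 0.1)])
    def test_coefficients_are_the_event_probabilities(self, abg):
        a, b, g = abg
        params = BranchingParams(alpha=a, beta=b, gamma=g, n_periods=1)
        assert offspring_pgf(params).tolist() == [a, b, g]

    def test_unnormalised_probabilities_rejected(self):
        with pytest.raises(ParameterError):
            BranchingParams(alpha=0.6, beta=0.6, gamma=0.1, n_periods=1)


class TestCopyNumberPmf:
    def test_no_time_steps_is_point_mass_at_one(self):
        pmf = copy_number_pmf(BranchingParams.symmetric(0.3, 0))
        assert pmf.tolist() == [0.0, 1.0]

    @pytest.mark.parametrize("m", [1, 3, 6])
    def test_deterministic_doubling_gives_two_copies(self, m):
        pmf = copy_number_pmf(BranchingParams.symmetric(0.0, 6, wgd_time=m))
        assert pmf[2] == pytest.approx(1.0)
        assert np.count_nonzero(pmf) == 1

    def test_two_period_symmetric_example(self):
        pmf = copy_number_pmf(BranchingParams.symmetric(0.1, 2))
        assert pmf == pytest.approx([0.181, 0.656, 0.146, 0.016, 0.001],
                                    abs=5e-4)

    @pytest.mark.parametrize("alpha,gamma", [(0.1, 0.1), (0.25, 0.05), (0.0, 0.3)])
    @pytest.mark.parametrize("n,m", [(1, None), (2, None), (3, None),
                                     (3, 1), (3, 2), (3, 3)])
    def test_matches_exact_enumeration_for_small_n(self, alpha, gamma, n, m):
        """The pgf composition must agree with exhaustive forward enumeration
        of the population distribution in rational arithmetic."""
        a, g = Fraction(alpha).limit_denominator(100), Fraction(gamma).limit_denominator(100)
        exact = branching_pmf_exact(a, 1 - a - g, g, n, m)
        pmf = copy_number_pmf(BranchingParams(alpha=float(a), beta=float(1 - a - g),
                                              gamma=float(g), n_periods=n,
                                              wgd_time=m))
        for c, p in exact.items():
            assert pmf[c] == pytest.approx(float(p), abs=1e-12)
        mask = np.ones(len(pmf), bool)
        mask[list(exact)] = False
        assert np.all(pmf[mask] < 1e-12)

    def test_wgd_time_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            BranchingParams.symmetric(0.1, 3, wgd_time=4)
        with pytest.raises(ParameterError):
            BranchingParams.symmetric(0.1, 3, wgd_time=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rate=st.floats(0.0, 0.5), n=st.integers(0, 5),
           frac=st.floats(0.0, 1.0))
    def test_mass_conservation_property(self, rate, n, frac):
        m = None if n == 0 else max(1, round(frac * n))
        pmf = copy_number_pmf(BranchingParams.symmetric(rate, n, wgd_time=m))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pmf >= 0)
        assert len(pmf) - 1 <= 2 ** (n + 1)

    def test_wgd_doubles_the_support_bound(self):
        for n in (2, 4, 6):
            without = copy_number_pmf(BranchingParams.symmetric(0.2, n))
            with_wgd = copy_number_pmf(BranchingParams.symmetric(0.2, n, wgd_time=n // 2))
            assert len(without) - 1 == 2 ** n
            assert len(with_wgd) - 1 == 2 * (2 ** n)

    def test_forward_simulation_agrees_with_pmf(self):
        """Total-variation distance to a large forward simulation is small."""
        params = BranchingParams.symmetric(0.1, 6, wgd_time=3)
        pmf = copy_number_pmf(params)
        rng = np.random.default_rng(42)
        counts = simulate_arm_counts(params, 100_000, rng)
        empirical = np.bincount(counts, minlength=len(pmf)) / len(counts)
        tv = 0.5 * np.abs(empirical[:len(pmf)] - pmf).sum()
        assert tv < 0.01


class TestMaxTotalCopyNumber:
    @pytest.mark.parametrize("n,wgd,expected", [(6, True, 256), (0, False, 2),
                                                (3, False, 16)])
    def test_closed_form(self, n, wgd, expected):
        assert max_total_copy_number(n, wgd) == expected

    def test_agrees_with_pmf_support(self):
        pmf = copy_number_pmf(BranchingParams.symmetric(0.2, 3))
        assert 2 * (len(pmf) - 1) == max_total_copy_number(3, False)

    def test_negative_periods_rejected(self):
        with pytest.raises(ParameterError):
            max_total_copy_number(-1, False)


class TestLogLikelihood:
    def test_identity_evolution_diploid_is_certain(self):
        profile = uniform_profile((1, 1), n_arms=1)
        assert log_likelihood(profile, BranchingParams.symmetric(0.0, 6)) == 0.0

    def test_pure_doubling_matches_tetraploid(self):
        profile = uniform_profile((2, 2), n_arms=1)
        params = BranchingParams.symmetric(0.0, 6, wgd_time=1)
        assert log_likelihood(profile, params) == 0.0

    def test_two_period_example_decomposes_per_allele(self):
        exact = branching_pmf_exact(Fraction(1, 10), Fraction(8, 10),
                                    Fraction(1, 10), 2)
        expected = math.log(float(exact[2])) + math.log(float(exact[1]))
        profile = ArmCNProfile(sample_id="s", arms={"a0": (2, 1)})
        got = log_likelihood(profile, BranchingParams.symmetric(0.1, 2))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_probability_state_gives_minus_inf(self):
        profile = uniform_profile((2, 1), n_arms=1)
        assert log_likelihood(profile, BranchingParams.symmetric(0.0, 6)) == -math.inf

    def test_state_beyond_support_raises(self):
        profile = ArmCNProfile(sample_id="s", arms={"a0": (5, 1)})
        with pytest.raises(UnrepresentableStateError, match="a0"):
            log_likelihood(profile, BranchingParams.symmetric(0.1, 1))


class TestFitModel:
    def test_diploid_profile_needs_no_events(self):
        fit = fit_model(uniform_profile((1, 1)), with_wgd=False)
        assert fit.params.alpha == pytest.approx(0.0, abs=1e-4)
        assert fit.log_likelihood == pytest.approx(0.0, abs=1e-6)
        assert fit.k == 1

    def test_tetraploid_profile_is_pure_doubling(self):
        fit = fit_model(uniform_profile((2, 2)), with_wgd=True)
        assert fit.params.alpha == pytest.approx(0.0, abs=1e-4)
        assert fit.log_likelihood == pytest.approx(0.0, abs=1e-6)
        assert fit.k == 2

    def test_unconstrained_parameter_counts(self):
        profile = uniform_profile((2, 1), n_arms=8)
        assert fit_model(profile, with_wgd=True, constrained=False).k == 3
        assert fit_model(profile, with_wgd=False, constrained=False).k == 2

    def test_aic_identity(self):
        fit = fit_model(uniform_profile((2, 1), n_arms=8), with_wgd=False)
        assert fit.aic == 2 * fit.k - 2 * fit.log_likelihood

    def test_undetermined_profile_rejected(self):
        with pytest.raises(FitError):
            fit_model(ArmCNProfile(sample_id="s", arms={"a0": None}),
                      with_wgd=False)

    def test_rate_recovery_from_simulations(self):
        """Constrained MLE recovers the simulation rate on 39-arm profiles."""
        rng = np.random.default_rng(7)
        params = BranchingParams.symmetric(0.05, 6)
        errors = []
        for _ in range(30):
            profile = simulate_arm_profile(params, 39, rng)
            fit = fit_model(profile, with_wgd=False)
            errors.append(abs(fit.params.alpha - 0.05))
        assert np.mean(errors) < 0.02


class TestSelectModel:
    def _fits(self, ll_wgd, ll_nonwgd, n_arms=4):
        p_w = BranchingParams.symmetric(0.1, 6, wgd_time=3)
        p_nw = BranchingParams.symmetric(0.1, 6)
        fw = FitResult(model="wgd", params=p_w, log_likelihood=ll_wgd, k=2,
                       aic=4 - 2 * ll_wgd, sample_id="s", n_arms=n_arms)
        fnw = FitResult(model="non_wgd", params=p_nw, log_likelihood=ll_nonwgd,
                        k=1, aic=2 - 2 * ll_nonwgd, sample_id="s", n_arms=n_arms)
        return fw, fnw

    def test_equal_likelihood_pays_the_extra_parameter(self):
        sel = select_model(*self._fits(-10.0, -10.0))
        assert sel.delta_aic == pytest.approx(-2.0)
        assert sel.selected == "non_wgd"

    def test_tetraploid_profile_supports_wgd(self):
        profile = uniform_profile((2, 2))
        sel = select_model(fit_model(profile, with_wgd=True),
                           fit_model(profile, with_wgd=False))
        assert sel.delta_aic > 0
        assert sel.selected == "wgd"

    def test_near_diploid_profile_rejects_wgd(self):
        arms = {f"a{i}": (1, 1) for i in range(38)}
        arms["a38"] = (2, 1)
        profile = ArmCNProfile(sample_id="s", arms=arms)
        sel = select_model(fit_model(profile, with_wgd=True),
                           fit_model(profile, with_wgd=False))
        assert sel.selected == "non_wgd"

    def test_mismatched_profiles_rejected(self):
        fw, _ = self._fits(-1.0, -1.0, n_arms=4)
        _, fnw = self._fits(-1.0, -1.0, n_arms=5)
        with pytest.raises(ValidationError):
            select_model(fw, fnw)


class TestSummarizeArms:
    def _arms(self, hg19_arms):
        return hg19_arms

    def test_full_coverage_single_state(self, hg19_arms):
        chrom, start, end = hg19_arms.interval("8q")
        table = segment_table_from_records("s", [(chrom, start, end, 3, 2)])
        profile = summarize_arms(table, hg19_arms)
        assert profile.arms["8q"] == (3, 2)

    def test_length_weighted_mode(self, hg19_arms):
        chrom, start, end = hg19_arms.interval("8q")
        split = start + int(0.7 * (end - start))
        table = segment_table_from_records(
            "s", [(chrom, start, split, 2, 1), (chrom, split, end, 2, 2)])
        assert summarize_arms(table, hg19_arms).arms["8q"] == (2, 1)

    def test_low_coverage_is_undetermined(self, hg19_arms):
        chrom, start, end = hg19_arms.interval("8q")
        stop = start + int(0.3 * (end - start))
        table = segment_table_from_records("s", [(chrom, start, stop, 2, 1)])
        assert summarize_arms(table, hg19_arms).arms["8q"] is None
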