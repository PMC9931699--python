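"""HDI, difference/effect-size draws, credibility, HDI/ROPE decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from citebest import (
    Decision,
    DecisionConfig,
    credibility_above_zero,
    decide,
    difference_draws,
    effect_size_draws,
    hdi,
    pairwise_credibility_matrix,
    summarize_comparison,
)


def hdi_oracle(samples, mass):
    """Independent brute force: scan every candidate interval start."""
    x = np.sort(np.asarray(samples, float))
    n = x.size
    k = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if width < best[0]:
            best = (width, (x[i], x[i + k - 1]))
    return best[1]


class TestHdi:
    def test_degenerate_samples(self):
        assert hdi(np.full(500, 5.0), 0.95) == (5.0, 5.0)

    def test_standard_normal_matches_quantile_oracle(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_exponential_hdi_starts_at_zero_and_beats_equal_tails(self, rng):
        x = rng.exponential(1.0, 1_000_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(0.0, abs=0.01)
        eq_lo, eq_hi = np.percentile(x, [2.5, 97.5])
        assert hi - lo < eq_hi - eq_lo

    @given(
        x=arrays(float, st.integers(100, 400),
                 elements=st.floats(-1e6, 1e6, allow_nan=False)),
        mass=st.floats(0.2, 0.99),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, x, mass):
        assert hdi(x, mass) == hdi_oracle(x, mass)

    @given(x=arrays(float, 300, elements=st.floats(-1e3, 1e3, allow_nan=False)))
    @settings(max_examples=30, deadline=None)
    def test_width_monotone_in_mass(self, x):
        widths = [np.diff(hdi(x, m))[0] for m in (0.5, 0.8, 0.95, 0.999)]
        assert widths == sorted(widths)
        lo, hi = hdi(x, 0.999999)
        assert (lo, hi) == (x.min(), x.max())

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50), 0.95)


class TestDifferenceDraws:
    def test_same_group_forbidden(self, fitted_trace):
        with pytest.raises(ValueError):
            difference_draws(fitted_trace, 0, 0)

    def test_unknown_group_rejected(self, fitted_trace):
        with pytest.raises(KeyError):
            difference_draws(fitted_trace, "nope", 0)

    def test_antisymmetry(self, fitted_trace):
        m12, s12 = difference_draws(fitted_trace, 0, 1)
        m21, s21 = difference_draws(fitted_trace, 1, 0)
        np.testing.assert_allclose(m12, -m21)
        np.testing.assert_allclose(s12, -s21)

    def test_constant_trace_gives_constant_diff(self, fitted_trace):
        import dataclasses

        mu = np.zeros_like(fitted_trace.mu)
        mu[:, :, 0] = 3.0
        mu[:, :, 1] = 1.0
        tr = dataclasses.replace(fitted_trace, mu=mu)
        m, _ = difference_draws(tr, 0, 1)
        np.testing.assert_array_equal(m, 2.0)


class TestEffectSize:
    def test_hand_computed_pooled_sd(self, fitted_trace):
        # n1=3, n2=2, sigma=(2,4): sigma_pooled = sqrt((2*4 + 1*16)/3) = sqrt(8)
        import dataclasses

        sigma = np.zeros_like(fitted_trace.sigma)
        sigma[:, :, 0] = 2.0
        sigma[:, :, 1] = 4.0
        mu = np.zeros_like(fitted_trace.mu)
        mu[:, :, 0] = 1.0
        tr = dataclasses.replace(fitted_trace, mu=mu, sigma=sigma)
        d = effect_size_draws(tr, 0, 1, n1=3, n2=2)
        np.testing.assert_allclose(d, 1.0 / np.sqrt(8.0))

    def test_equal_n_equal_sigma_collapses(self, fitted_trace):
        import dataclasses

        sigma = np.full_like(fitted_trace.sigma, 5.0)
        tr = dataclasses.replace(fitted_trace, sigma=sigma)
        d = effect_size_draws(tr, 0, 1, n1=50, n2=50)
        m, _ = difference_draws(tr, 0, 1)
        np.testing.assert_allclose(d, m / 5.0)

    def test_zero_mean_difference_gives_zero_effect(self, fitted_trace):
        import dataclasses

        tr = dataclasses.replace(fitted_trace, mu=np.zeros_like(fitted_trace.mu))
        np.testing.assert_array_equal(effect_size_draws(tr, 0, 1, 10, 10), 0.0)

    def test_scale_equivariance_cancels(self, fitted_trace):
        # rescaling both groups' data rescales mu and sigma draws alike,
        # leaving Cohen's d invariant
        import dataclasses

        scaled = dataclasses.replace(
            fitted_trace, mu=fitted_trace.mu * 7.0, sigma=fitted_trace.sigma * 7.0
        )
        np.testing.assert_allclose(
            effect_size_draws(scaled, 0, 1, 30, 20),
            effect_size_draws(fitted_trace, 0, 1, 30, 20),
        )

    def test_degenerate_sizes_rejected(self, fitted_trace):
        with pytest.raises(ValueError):
            effect_size_draws(fitted_trace, 0, 1, n1=1, n2=1)


class TestCredibility:
    @pytest.mark.parametrize(
        "samples, expected",
        [([1.0, 2.0, 3.0], 100.0), ([-1.0, 1.0], 50.0), ([-2.0, -1.0], 0.0),
         ([0.0, 1.0], 50.0)],  # exact zeros count as not above
    )
    def test_basic_masses(self, samples, expected):
        assert credibility_above_zero(np.array(samples)) == expected

    @given(x=arrays(float, st.integers(1, 200),
                    elements=st.floats(-100, 100, allow_nan=False).filter(lambda v: v != 0)))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_sums_to_100(self, x):
        assert credibility_above_zero(x) + credibility_above_zero(-x) == pytest.approx(100.0)


class TestDecide:
    CFG = DecisionConfig()

    @pytest.mark.parametrize(
        "mu_hdi, eff_hdi, expected",
        [
            ((0.044, 6.9), (0.1, 0.8), Decision.REJECT_H0_GROUP1_HIGHER),
            ((-6.9, -0.044), (-0.8, -0.1), Decision.REJECT_H0_GROUP2_HIGHER),
            ((-1.0, 2.0), (-0.1, 0.1), Decision.ACCEPT_H0),
            ((-5.6, 4.5), (-0.5, 0.4), Decision.UNDECIDED),
            # ROPE only accepts, never widens rejection
            ((-0.1, 0.5), (0.25, 0.9), Decision.UNDECIDED),
            ((-1.0, 2.0), (-0.2, 0.2), Decision.ACCEPT_H0),  # inclusive bounds
        ],
    )
    def test_four_way_rule(self, mu_hdi, eff_hdi, expected):
        assert decide(mu_hdi, eff_hdi, self.CFG) is expected

    @given(
        lo=st.floats(-10, 10), width=st.floats(0, 10), shift=st.floats(0, 20),
        e_lo=st.floats(-1, 1), e_width=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_upward_shift_never_flips_toward_group2(self, lo, width, shift, e_lo, e_width):
        eff = (e_lo, e_lo + e_width)
        before = decide((lo, lo + width), eff, self.CFG)
        after = decide((lo + shift, lo + width + shift), eff, self.CFG)
        if before is Decision.REJECT_H0_GROUP1_HIGHER:
            assert after is Decision.REJECT_H0_GROUP1_HIGHER
        assert not (
            before is not Decision.REJECT_H0_GROUP2_HIGHER
            and after is Decision.REJECT_H0_GROUP2_HIGHER
        )


class TestSummaryAndMatrix:
    def test_summary_is_internally_consistent(self, fitted_trace):
        s = summarize_comparison(fitted_trace, 0, 1)
        assert s.n1 == s.n2 == 200
        assert s.mean_diff.hdi_low <= s.mean_diff.mean <= s.mean_diff.hdi_high
        assert 0.0 <= s.mean_diff.credibility_above_zero <= 100.0
        # groups were simulated 10 apart: decisive rejection expected
        assert s.decision is Decision.REJECT_H0_GROUP1_HIGHER

    def test_pairwise_matrix_antisymmetry(self, fitted_trace):
        m = pairwise_credibility_matrix(fitted_trace)
        assert np.isnan(m.iloc[0, 0]) and np.isnan(m.iloc[1, 1])
        assert m.iloc[0, 1] + m.iloc[1, 0] == pytest.approx(100.0)

    def test_identically_simulated_groups_near_50(self):
        from citebest import GroupDataset, ModelSpec, generate_group, \
            pooled_prior_spec, sample_posterior

        g1 = GroupDataset("a", generate_group(150, 10, 4, 8, seed=21))
        g2 = GroupDataset("b", generate_group(150, 10, 4, 8, seed=22))
        spec = ModelSpec(groups=(g1, g2), prior=pooled_prior_spec([g1, g2]))
        tr = sample_posterior(spec, draws=2000, chains=2, seed=5, tune=300)
        m = pairwise_credibility_matrix(tr)
        assert 10 < m.iloc[0, 1] < 90  # exchangeable groups: no decisive mass

    def test_ordered_groups_give_ordered_credibilities(self):
        from citebest import GroupDataset, ModelSpec, generate_group, \
            pooled_prior_spec, sample_posterior

        groups = tuple(
            GroupDataset(f"m{k}", generate_group(100, 5.0 * k, 1.0, 20.0, seed=30 + k))
            for k in range(3)
        )
        spec = ModelSpec(groups=groups, prior=pooled_prior_spec(groups))
        tr = sample_posterior(spec, draws=2000, chains=2, seed=9, tune=300)
        m = pairwise_credibility_matrix(tr)
        for i in range(3):
            for j in range(3):
                if i > j:
                    assert m.iloc[i, j] > 95.0
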