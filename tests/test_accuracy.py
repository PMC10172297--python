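import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sirrank.accuracy import (
    QuartileAccuracySimulator,
    flag_upper_quartile,
    min_events_for_target,
    simulate_dataset,
)
from sirrank.glmm import ConditionalParams


class TestFlagUpperQuartile:
    def test_one_to_eight(self):
        flags = flag_upper_quartile(np.arange(1.0, 9.0))
        # 75th percentile is 6.25: exactly the top two exceed it
        np.testing.assert_array_equal(flags, [False] * 6 + [True] * 2)

    def test_149_distinct_values_flags_37(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(np.linspace(0.1, 5.0, 149))
        flags = flag_upper_quartile(values)
        assert flags.sum() == 37
        assert (~flags).sum() == 112

    def test_all_equal_none_flagged(self):
        with pytest.warns(UserWarning, match="75th percentile"):
            flags = flag_upper_quartile(np.full(10, 3.3))
        assert not flags.any()

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60, unique=True))
    def test_at_most_a_quarter_flagged_when_distinct(self, values):
        import math

        flags = flag_upper_quartile(np.array(values))
        assert 1 <= flags.sum() <= math.ceil(len(values) / 4)


class TestSimulateDataset:
    def test_symmetric_null_rate(self):
        gidx = np.zeros(10_000, dtype=np.intp)
        cond = ConditionalParams(0.0, np.array([]), 0.0)
        rng = np.random.default_rng(1)
        _, y = simulate_dataset(np.empty((10_000, 0)), gidx, 1, cond, rng)
        assert y.mean() == pytest.approx(0.5, abs=0.02)

    def test_extreme_intercept_gives_no_events(self):
        gidx = np.zeros(5_000, dtype=np.intp)
        cond = ConditionalParams(-20.0, np.array([]), 0.0)
        rng = np.random.default_rng(2)
        _, y = simulate_dataset(np.empty((5_000, 0)), gidx, 1, cond, rng)
        assert y.sum() == 0

    def test_hospital_rate_variance_matches_closed_form(self):
        """Across pools, the empirical variance of hospital event rates
        should match pi(1-pi)/n_H + var of true rates (cross-check with
        the heterogeneity module's closed form)."""
        from sirrank.heterogeneity import expected_empirical_variance, harmonic_mean

        m, n_i = 60, 120
        gidx = np.repeat(np.arange(m), n_i)
        X = np.empty((m * n_i, 0))
        alpha, sigma = -1.5, 0.25
        rng = np.random.default_rng(3)
        s2s, rate_vars = [], []
        for _ in range(300):
            a, y = simulate_dataset(X, gidx, m, ConditionalParams(alpha, np.array([]), sigma**2), rng)
            rates = np.bincount(gidx, weights=y, minlength=m) / n_i
            s2s.append(np.var(rates, ddof=1))
            rate_vars.append(np.var(1 / (1 + np.exp(-a)), ddof=1))
        pi = 1 / (1 + np.exp(-alpha))
        # on the rate scale the between-hospital variance is that of expit(alpha_i)
        expected = expected_empirical_variance(pi, harmonic_mean([n_i] * m), np.mean(rate_vars))
        assert np.mean(s2s) == pytest.approx(expected, rel=0.05)


def _simple_pool(m, n_i, alpha, sigma):
    gidx = np.repeat(np.arange(m), n_i)
    rng = np.random.default_rng(10)
    X = rng.normal(size=(m * n_i, 1))
    cond = ConditionalParams(alpha, np.array([0.3]), sigma**2)
    return X, gidx, cond


class TestAlgorithmOne:
    def test_counts_sum_to_k_and_metrics_in_unit_interval(self):
        X, gidx, cond = _simple_pool(12, 150, -2.0, 0.6)
        sim = QuartileAccuracySimulator(n_datasets=150, random_state=7)
        sim.fit(X, gidx, cond)
        tab = sim.results_
        assert (tab[["n_tp", "n_tn", "n_fp", "n_fn"]].sum(axis=1) == 150).all()
        for col in ("power", "fpr", "ppv", "npv"):
            vals = tab[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_seed_reproducibility_bit_for_bit(self):
        X, gidx, cond = _simple_pool(8, 100, -1.5, 0.5)
        a = QuartileAccuracySimulator(n_datasets=60, random_state=5).fit(X, gidx, cond)
        b = QuartileAccuracySimulator(n_datasets=60, random_state=5).fit(X, gidx, cond)
        pd.testing.assert_frame_equal(a.results_, b.results_)

    def test_zero_heterogeneity_gives_undefined_power(self):
        X, gidx, cond = _simple_pool(8, 100, -1.5, 0.0)
        sim = QuartileAccuracySimulator(n_datasets=40, random_state=3).fit(X, gidx, cond)
        assert np.isnan(sim.power_).all()  # no hospital is ever truly flagged
        assert np.allclose(sim.npv_, 1.0)  # and none is ever missed

    def test_large_information_limit(self):
        """Big equal-volume hospitals with strong heterogeneity are ranked
        almost perfectly."""
        m, n_i = 8, 2000
        gidx = np.repeat(np.arange(m), n_i)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(m * n_i, 1))
        cond = ConditionalParams(-1.4, np.array([0.3]), 1.0)  # rate ~20%
        sim = QuartileAccuracySimulator(n_datasets=500, random_state=13).fit(X, gidx, cond)
        assert (sim.power_ > 0.8).all()
        assert (sim.fpr_ < 0.1).all()

    def test_true_flag_fraction_matches_exchangeability(self):
        """Each hospital's alpha draw lands in the worst quartile in
        (m/4-ish)/m of datasets: 37/149 exactly on average for m=149."""
        m, n_i, K = 149, 6, 300
        gidx = np.repeat(np.arange(m), n_i)
        rng = np.random.default_rng(17)
        X = rng.normal(size=(m * n_i, 1))
        cond = ConditionalParams(-1.2, np.array([0.2]), 1.0)
        sim = QuartileAccuracySimulator(n_datasets=K, random_state=19).fit(X, gidx, cond)
        frac = (sim.results_["n_tp"] + sim.results_["n_fn"]) / K
        assert frac.mean() == pytest.approx(37 / 149, abs=1e-12)
        assert np.max(np.abs(frac - 37 / 149)) < 0.12  # ~4.7 binomial SDs

    def test_exclusion_filter_blanks_low_volume_hospitals(self):
        m = 10
        volumes = np.array([4] * 3 + [400] * 7)
        gidx = np.repeat(np.arange(m), volumes)
        rng = np.random.default_rng(23)
        X = rng.normal(size=(volumes.sum(), 1))
        cond = ConditionalParams(-2.5, np.array([0.3]), 0.5**2)
        sim = QuartileAccuracySimulator(
            n_datasets=50, random_state=29, exclude_below_predicted=1.0
        ).fit(X, gidx, cond)
        assert (~sim.include_mask_[:3]).all()
        assert np.isnan(sim.power_[:3]).all()


class TestMinEventsForTarget:
    def test_monotone_frontier(self):
        x = [1, 2, 5, 10, 30]
        power = [0.2, 0.4, 0.6, 0.81, 0.85]
        assert min_events_for_target(x, power, 0.8, ">=") == 10

    def test_non_monotone_frontier(self):
        x = [1, 2, 5, 10, 30]
        power = [0.2, 0.85, 0.6, 0.81, 0.9]
        assert min_events_for_target(x, power, 0.8, ">=") == 10

    def test_no_hospital_meets_target(self):
        assert min_events_for_target([1, 2], [0.1, 0.2], 0.8, ">=") is None

    @given(
        st.lists(
            st.tuples(st.integers(1, 30), st.floats(0, 1)), min_size=1, max_size=20
        )
    )
    def test_matches_enumeration_oracle(self, pairs):
        x = np.array([p[0] for p in pairs], dtype=float)
        v = np.array([p[1] for p in pairs])
        got = min_events_for_target(x, v, 0.5, ">=")
        # brute force: try every candidate threshold in ascending order
        best = None
        for cand in sorted(set(x)):
            if np.all(v[x >= cand] >= 0.5):
                best = cand
                break
        assert got == best
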