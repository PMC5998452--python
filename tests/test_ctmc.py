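"""CTMC: transition probabilities, panel likelihood, MLE, CIs, curves."""

import numpy as np
import pytest

import stageflow as sf
from stageflow.ctmc import CTMCError
from stageflow.staging import TransitionCountMatrix

from conftest import RECOVERY_INIT, RECOVERY_RATES, random_intensity


def series_expm(A, terms=50):
    """Truncated power-series oracle for the matrix exponential."""
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for n in range(1, terms):
        term = term @ A / n
        out = out + term
    return out


def counts_matrix(entries, interval=13.0):
    n = np.zeros((4, 4), int)
    for (l, k), v in entries.items():
        n[l - 1, k - 1] = v
    return TransitionCountMatrix(counts=n, interval=interval)


class TestIntensityMatrix:
    def test_rows_sum_to_zero_and_absorbing(self):
        Q = sf.IntensityMatrix.from_rates(RECOVERY_RATES)
        assert np.allclose(Q.matrix.sum(axis=1), 0)
        assert np.all(Q.matrix[3] == 0)

    def test_invalid_matrices_rejected(self):
        bad = np.zeros((4, 4))
        bad[0, 1], bad[0, 0] = 0.1, -0.05  # row sum != 0
        with pytest.raises(CTMCError):
            sf.IntensityMatrix(matrix=bad)
        bad2 = np.zeros((4, 4))
        bad2[0, 1], bad2[0, 0] = -0.1, 0.1  # negative off-diagonal
        with pytest.raises(CTMCError):
            sf.IntensityMatrix(matrix=bad2)


class TestTransitionProbability:
    def test_identity_at_zero(self, recovery_Q):
        assert np.allclose(sf.transition_probability(recovery_Q, 0.0), np.eye(4))

    def test_single_exit_closed_form(self):
        Q = sf.IntensityMatrix.from_rates({"q14": 0.1})
        P = sf.transition_probability(Q, 13.0)
        assert P[0, 3] == pytest.approx(1 - np.exp(-1.3), abs=1e-12)

    def test_matches_series_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            Q = random_intensity(rng)
            P = sf.transition_probability(Q, 1.0)
            assert np.abs(P - series_expm(Q.matrix)).max() < 1e-8

    def test_stochastic_rows(self):
        rng = np.random.default_rng(1)
        for t in (0.5, 7.0, 26.0):
            P = sf.transition_probability(random_intensity(rng), t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= 0).all()
            assert np.allclose(P[3], [0, 0, 0, 1])

    def test_semigroup_property(self):
        """P(s + t) = P(s) P(t) for random generators on [0, 26]."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            Q = random_intensity(rng)
            s, t = rng.uniform(0, 26, size=2)
            left = sf.transition_probability(Q, s + t)
            right = sf.transition_probability(Q, s) @ sf.transition_probability(Q, t)
            assert np.abs(left - right).max() < 1e-8

    def test_negative_time_rejected(self, recovery_Q):
        with pytest.raises(CTMCError):
            sf.transition_probability(recovery_Q, -1.0)


class TestPanelLogLikelihood:
    def test_all_absorbed_is_zero(self):
        counts = counts_matrix({(4, 4): 50})
        Q = sf.IntensityMatrix.from_rates(RECOVERY_RATES)
        assert sf.panel_log_likelihood(Q, counts) == pytest.approx(0.0)

    def test_equals_per_cell_recomputation(self, recovery_Q):
        counts = counts_matrix({(1, 1): 30, (1, 2): 5, (2, 3): 7, (3, 4): 4})
        ll = sf.panel_log_likelihood(recovery_Q, counts)
        P = sf.transition_probability(recovery_Q, 13.0)
        brute = sum(
            counts.counts[l, k] * np.log(P[l, k])
            for l in range(4) for k in range(4) if counts.counts[l, k] > 0
        )
        assert ll == pytest.approx(brute, rel=1e-12)

    def test_structural_zero_gives_minus_inf(self):
        Q = sf.IntensityMatrix.from_rates({"q14": 0.1})  # no path 1 -> 2
        counts = counts_matrix({(1, 2): 3})
        assert sf.panel_log_likelihood(Q, counts) == -np.inf

    def test_panel_and_counts_entry_points_agree(self, recovery_Q):
        """Equal-interval likelihood depends on the panel only through
        its transition-count matrix."""
        spec = sf.SimulationSpec(group_sizes={"G": 80},
                                 intensities={"G": recovery_Q},
                                 initial_distributions={"G": RECOVERY_INIT},
                                 seed=2)
        panel, _ = sf.sample_ctmc_panel(spec)
        counts = sf.transition_counts(panel, "G")
        assert sf.panel_log_likelihood(recovery_Q, panel, group="G") == \
            pytest.approx(sf.panel_log_likelihood(recovery_Q, counts), rel=1e-12)


class TestFitCTMC:
    def test_two_state_closed_form(self):
        """n=100 subjects, 26 absorbed over one 13-week interval: the
        MLE is q = -ln(1 - 26/100)/13."""
        counts = counts_matrix({(1, 1): 74, (1, 4): 26})
        mask = np.zeros((4, 4), bool)
        mask[0, 3] = True
        fit = sf.fit_ctmc(counts, mask=mask, seed=0)
        assert fit.Q.rate(1, 4) == pytest.approx(-np.log(0.74) / 13, abs=1e-6)

    def test_no_evidence_rate_hits_floor(self):
        counts = counts_matrix({(1, 1): 50, (1, 4): 10, (2, 2): 40, (2, 4): 5,
                                (3, 3): 30, (3, 4): 5})
        fit = sf.fit_ctmc(counts, seed=0)
        # arrows among transient stages have no observed transitions
        assert fit.Q.rate(1, 2) <= 1e-6
        assert fit.Q.rate(2, 1) <= 1e-6

    def test_parameter_recovery(self, recovery_Q):
        spec = sf.SimulationSpec(group_sizes={"G": 2000},
                                 intensities={"G": recovery_Q},
                                 initial_distributions={"G": RECOVERY_INIT},
                                 seed=11)
        panel, _ = sf.sample_ctmc_panel(spec)
        fit = sf.fit_ctmc(panel, group="G", seed=3)
        assert fit.converged
        for (l, k) in fit.param_index:
            true = recovery_Q.matrix[l - 1, k - 1]
            assert fit.Q.rate(l, k) == pytest.approx(true, rel=0.35)

    def test_deterministic_given_seed(self, recovery_Q):
        spec = sf.SimulationSpec(group_sizes={"G": 300},
                                 intensities={"G": recovery_Q},
                                 initial_distributions={"G": RECOVERY_INIT},
                                 seed=4)
        panel, _ = sf.sample_ctmc_panel(spec)
        f1 = sf.fit_ctmc(panel, group="G", seed=5)
        f2 = sf.fit_ctmc(panel, group="G", seed=5)
        assert np.array_equal(f1.log_params, f2.log_params)

    def test_nothing_to_fit_errors(self):
        counts = counts_matrix({(1, 1): 90})
        with pytest.raises(CTMCError):
            sf.fit_ctmc(counts)


class TestSojournTimes:
    def test_reciprocal_of_exit_rate(self):
        Q = sf.IntensityMatrix.from_rates({"q12": 0.3, "q14": 0.2})
        s = sf.sojourn_times(Q)
        assert s[1] == pytest.approx(2.0)  # q11 = -0.5
        assert s[2] == np.inf  # no exits from stage 2
        assert s[4] == np.inf

    def test_exit_rate_implied_by_reference_sojourn(self):
        """A fit whose unmotivated sojourn is 15.883 weeks implies
        q11 = -1/15.883."""
        q11 = -1 / 15.883
        Q = sf.IntensityMatrix.from_rates({"q12": -q11 * 0.6, "q13": -q11 * 0.4})
        assert sf.sojourn_times(Q)[1] == pytest.approx(15.883, rel=1e-12)
        assert Q.matrix[0, 0] == pytest.approx(-0.06296, abs=5e-6)

    def test_monte_carlo_holding_times(self):
        """Sampled exponential holding times at rate 0.1 average to 10
        within 3 standard errors."""
        Q = sf.IntensityMatrix.from_rates({"q14": 0.1})
        rng = np.random.default_rng(123)
        n = 10000
        holds = []
        for _ in range(n):
            path = sf.synthdata.sample_path(Q, 1, np.inf, rng)
            holds.append(path[-1][0] if len(path) > 1 else np.nan)
        holds = np.array(holds)
        se = 10.0 / np.sqrt(n)
        assert abs(np.nanmean(holds) - 10.0) < 3 * se


@pytest.fixture(scope="module")
def small_fit(recovery_Q):
    spec = sf.SimulationSpec(group_sizes={"G": 500},
                             intensities={"G": recovery_Q},
                             initial_distributions={"G": RECOVERY_INIT},
                             seed=21)
    panel, _ = sf.sample_ctmc_panel(spec)
    return sf.fit_ctmc(panel, group="G", seed=1)


class TestSimulatedCI:
    def test_zero_covariance_degenerates_to_point(self, small_fit):
        import copy
        fit = copy.deepcopy(small_fit)
        fit.cov = np.zeros_like(fit.cov)
        cis = sf.ci_simulated(fit, draws=200, seed=0)
        for (l, k), (lo, hi) in cis["rates"].items():
            assert lo == pytest.approx(hi)
            assert lo == pytest.approx(fit.Q.rate(l, k), rel=1e-9)

    def test_bounds_are_percentiles_of_draws(self, small_fit):
        """Recount: the reported bounds equal an independently computed
        2.5/97.5 percentile of the same MVN draw."""
        cis = sf.ci_simulated(small_fit, draws=500, level=0.95, seed=7)
        w, V = np.linalg.eigh(small_fit.cov)
        cov = V @ np.diag(np.clip(w, 0, None)) @ V.T
        rng = np.random.default_rng(7)
        thetas = rng.multivariate_normal(small_fit.log_params, cov, size=500,
                                         method="eigh")
        rates = np.exp(thetas)
        for m, lk in enumerate(small_fit.param_index):
            lo, hi = cis["rates"][lk]
            assert lo == pytest.approx(np.percentile(rates[:, m], 2.5))
            assert hi == pytest.approx(np.percentile(rates[:, m], 97.5))

    def test_bounds_positive_and_reproducible(self, small_fit):
        a = sf.ci_simulated(small_fit, draws=300, seed=3)
        b = sf.ci_simulated(small_fit, draws=300, seed=3)
        assert a["rates"] == b["rates"]
        assert all(lo > 0 for lo, _ in a["rates"].values())
        assert all(lo > 0 for lo, _ in a["sojourn"].values())


class TestPrevalenceCurves:
    def test_absorbing_start_constant(self, recovery_Q):
        curves = sf.model_prevalence(recovery_Q, [0, 0, 0, 1])
        assert np.allclose(curves["stage4"], 100.0)
        assert np.allclose(curves[["stage1", "stage2", "stage3"]], 0.0)

    def test_baseline_equals_init(self, recovery_Q):
        init = np.array([0.5, 0.3, 0.2, 0.0])
        curves = sf.model_prevalence(recovery_Q, init)
        assert np.allclose(curves.iloc[0, 1:5], 100 * init)

    def test_rows_sum_to_100_and_stage4_monotone(self, recovery_Q):
        curves = sf.model_prevalence(recovery_Q, [0.4, 0.3, 0.3, 0.0])
        assert np.allclose(curves.iloc[:, 1:5].sum(axis=1), 100.0, atol=1e-8)
        assert (np.diff(curves["stage4"]) >= -1e-10).all()

    def test_endpoint_matches_independent_recomputation(self, recovery_Q):
        init = np.array([0.6, 0.2, 0.2, 0.0])
        curves = sf.model_prevalence(recovery_Q, init)
        P26 = sf.transition_probability(recovery_Q, 26.0)
        assert np.allclose(curves.iloc[-1, 1:5], 100 * init @ P26, atol=1e-10)


class TestAbsorptionProbability:
    def test_single_exit_closed_form(self):
        Q = sf.IntensityMatrix.from_rates({"q24": 0.05})
        curve = sf.absorption_probability(Q, 2, grid=np.arange(0, 27))
        expected = 1 - np.exp(-0.05 * np.arange(0, 27))
        assert np.allclose(curve["p_absorb"], expected, atol=1e-12)

    def test_monotone_in_unit_interval_from_zero(self, recovery_Q):
        for stage in (2, 3):
            curve = sf.absorption_probability(recovery_Q, stage)
            p = curve["p_absorb"].to_numpy()
            assert p[0] == 0.0
            assert (np.diff(p) >= -1e-12).all()
            assert ((0 <= p) & (p <= 1)).all()

    def test_matches_matrix_entry(self, recovery_Q):
        curve = sf.absorption_probability(recovery_Q, 3, grid=[0, 5, 13, 26])
        for t, p in zip(curve["week"], curve["p_absorb"]):
            P = sf.transition_probability(recovery_Q, t)
            assert p == pytest.approx(P[2, 3], abs=1e-12)

    def test_communicating_chain_limits_to_one(self, recovery_Q):
        curve = sf.absorption_probability(recovery_Q, 2, grid=[2000.0])
        assert curve["p_absorb"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_from_absorbing_state_is_one(self, recovery_Q):
        curve = sf.absorption_probability(recovery_Q, 4, grid=[0, 10])
        assert (curve["p_absorb"] == 1.0).all()
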