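import numpy as np
import pytest
from scipy.stats import norm

from msitr.censoring import CensoringHazard, nelson_aalen_censoring
from msitr.data import PreferenceWeight, TrialDataset, estimate_propensity
from msitr.inference import (
    covariance_matrix,
    estimate_value,
    influence_functions,
    jackknife_value,
    simultaneous_band,
    value_report,
)
from msitr.owl import DecisionFunction, fit_linear, surrogate_risk, case_weights
from msitr.simulate import SimScenario, simulate_trial

from _oracles import oracle_linear_objective
from conftest import make_record

NO_CENS = CensoringHazard(np.empty(0), np.empty(0))


def four_subject_dataset():
    """No censoring; treated utilities {2,4}, control {1,3} (time in state 2)."""
    recs = []
    for u, a in [(2.0, 1), (4.0, 1), (1.0, -1), (3.0, -1)]:
        recs.append(
            make_record([(0.0, 1), (0.2, 2), (0.2 + u, 3)], 0.2 + u, 1, a=a,
                        z=[0.1 * u])
        )
    return TrialDataset(recs, tau=5.0, n_states=3)


class TestEstimateValue:
    def test_fixed_rule_hand_arithmetic(self, w_response):
        data = four_subject_dataset()
        assert estimate_value(data, 1, w_response, NO_CENS, 0.5) == pytest.approx(3.0)
        assert estimate_value(data, -1, w_response, NO_CENS, 0.5) == pytest.approx(2.0)

    def test_rule_matching_no_arm_gives_zero(self, w_response):
        data = four_subject_dataset()
        rule = lambda z: -np.array([r.a for r in data.records])
        assert estimate_value(data, rule, w_response, NO_CENS, 0.5) == 0.0

    def test_value_plus_zero_one_risk_identity(self, w_response):
        """V_hat(sgn f) + 0-1 risk of f = total weighted mass, any dataset."""
        for seed in (0, 1, 2):
            data = simulate_trial(SimScenario(1, -1.0, 60, seed=seed))
            pi = estimate_propensity(data)
            h = nelson_aalen_censoring(data)
            f = DecisionFunction(
                "linear", intercept=0.3, slope=np.array([1.0, -0.5])
            )
            U, v = case_weights(data, w_response, h, pi)
            value = estimate_value(data, f, w_response, h, pi)
            margins = data.a_vector * f(data.z_matrix)
            risk01 = float(np.mean(v * (margins < 0)))
            assert value + risk01 == pytest.approx(np.mean(v))


class TestJackknife:
    def test_stable_fits_reduce_to_plugin(self, w_response):
        # strong separation: every leave-one-out rule equals the full rule
        recs = []
        for i, (z, a) in enumerate([(1.0, 1), (-1.0, -1)] * 6):
            u = 2.0 if np.sign(z) == np.sign(a) else 0.0
            if u > 0:
                recs.append(make_record(
                    [(0.0, 1), (0.5, 2), (0.5 + u, 3)], 0.5 + u, 1, a=a, z=[z]))
            else:
                recs.append(make_record([(0.0, 1), (0.5, 3)], 0.5, 1, a=a, z=[z]))
        data = TrialDataset(recs, tau=3.0, n_states=3)
        pi = estimate_propensity(data)
        fit = fit_linear(data, w_response, 0.01, NO_CENS, pi)
        plugin = estimate_value(data, fit.f, w_response, NO_CENS, pi)
        jk = jackknife_value(data, w_response, 0.01)
        assert jk == pytest.approx(plugin, rel=1e-9)

    def test_matches_brute_force_refits(self, w_response):
        """n=5: literal leave-one-out refits via the independent SLSQP oracle."""
        data = simulate_trial(SimScenario(1, -1.6, 5, seed=12))
        lam = 0.3
        pi_full = estimate_propensity(data)
        h_full = nelson_aalen_censoring(data)
        total = 0.0
        for i in range(5):
            rest = TrialDataset(
                [r for j, r in enumerate(data.records) if j != i],
                tau=data.tau, n_states=3,
            )
            pi_i = estimate_propensity(rest)
            h_i = nelson_aalen_censoring(rest)
            _, v = case_weights(rest, w_response, h_i, pi_i)
            _, slope, b0 = oracle_linear_objective(
                rest.z_matrix, rest.a_vector, v, lam
            )
            rec = data.records[i]
            from msitr.utility import ipcw_utility
            U_i = ipcw_utility(rec, w_response, h_full, data.tau)
            d_i = 1 if b0 + rec.z @ slope >= 0 else -1
            denom = pi_full if rec.a == 1 else 1 - pi_full
            total += U_i * (rec.a == d_i) / denom
        brute = total / 5
        jk = jackknife_value(data, w_response, lam)
        assert jk == pytest.approx(brute, abs=1e-6)


class TestInfluenceFunctions:
    def test_no_censoring_known_pi_reduces_to_centered_summand(self, w_response):
        data = four_subject_dataset()
        iv = influence_functions(data, 1, w_response, NO_CENS, 0.5, pi_fixed=True)
        U = np.array([2.0, 4.0, 1.0, 3.0])
        a = np.array([1, 1, -1, -1])
        g = U * (a == 1) / 0.5
        np.testing.assert_allclose(iv.psi, g - g.mean())
        assert iv.sigma2 == pytest.approx(np.mean((g - g.mean()) ** 2))

    def test_mean_influence_near_zero_on_simulated_data(self, w_response):
        data = simulate_trial(SimScenario(1, -1.0, 400, seed=3))
        pi = estimate_propensity(data)
        h = nelson_aalen_censoring(data)
        iv = influence_functions(data, 1, w_response, h, pi)
        assert abs(iv.psi.mean()) < 3 * iv.psi.std(ddof=1) / np.sqrt(len(data))

    def test_se_matches_bootstrap_oracle(self, w_response):
        """Influence-function SE vs a 500-replicate nonparametric bootstrap
        of the value estimate for a fixed fitted rule (S1, n=300, ~45%
        censoring); agreement within 15% relative error."""
        n = 300
        data = simulate_trial(SimScenario(1, -1.0, n, seed=7))
        pi = estimate_propensity(data)
        h = nelson_aalen_censoring(data)
        fit = fit_linear(data, w_response, n**-0.5, h, pi)
        se_if = influence_functions(data, fit.f, w_response, h, pi).se
        rng = np.random.default_rng(99)
        boots = []
        for _ in range(500):
            idx = rng.integers(0, n, n)
            bs = TrialDataset([data.records[i] for i in idx], data.tau, 3)
            try:
                pi_b = estimate_propensity(bs)
            except Exception:
                continue
            h_b = nelson_aalen_censoring(bs)
            boots.append(estimate_value(bs, fit.f, w_response, h_b, pi_b))
        se_boot = np.std(boots, ddof=1)
        assert abs(se_if - se_boot) / se_boot < 0.15

    def test_mean_se_matches_monte_carlo_sd(self, w_response):
        """Mean estimated SE vs Monte Carlo SD of the value estimate over 500
        replications (S1, n=400, ~30% censoring, fixed rule d = +1); within
        10%."""
        v_hats, ses = [], []
        for rep in range(500):
            data = simulate_trial(SimScenario(1, -1.6, 400, seed=10_000 + rep))
            pi = estimate_propensity(data)
            h = nelson_aalen_censoring(data)
            v_hats.append(estimate_value(data, 1, w_response, h, pi))
            ses.append(influence_functions(data, 1, w_response, h, pi).se)
        mcsd = np.std(v_hats, ddof=1)
        assert abs(np.mean(ses) - mcsd) / mcsd < 0.10


class TestCovariance:
    def test_single_entry_equals_variance(self, w_response):
        data = simulate_trial(SimScenario(1, -1.0, 80, seed=4))
        pi = estimate_propensity(data)
        h = nelson_aalen_censoring(data)
        omega = covariance_matrix(data, [(1, w_response)], h, pi)
        iv = influence_functions(data, 1, w_response, h, pi)
        assert omega.shape == (1, 1)
        assert omega[0, 0] == pytest.approx(iv.sigma2)

    def test_duplicated_entry_perfectly_correlated(self, w_response):
        data = simulate_trial(SimScenario(1, -1.0, 80, seed=4))
        pi = estimate_propensity(data)
        h = nelson_aalen_censoring(data)
        omega = covariance_matrix(
            data, [(1, w_response), (1, w_response)], h, pi
        )
        assert omega[0, 0] == pytest.approx(omega[0, 1])
        assert np.linalg.matrix_rank(omega, tol=1e-10 * omega[0, 0]) == 1

    def test_disjoint_weights_nearly_uncorrelated(self):
        """Weights supported on different states, with state-1 and state-2
        occupancy varying on disjoint subject halves.  Utilities are sparse
        (rare long stays), so the unavoidable -V1*V2 cross-moment of the
        one-sample estimators is negligible against the variances and the
        off-diagonal covariance is approximately zero."""
        rng = np.random.default_rng(11)
        recs = []
        for i in range(600):
            a = 1 if rng.uniform() < 0.5 else -1
            long_stay = rng.uniform() < 0.05
            if i % 2 == 0:  # state-1 time varies, never responds
                t1 = 2.5 if long_stay else 0.01
                recs.append(make_record([(0.0, 1), (t1, 3)], t1, 1, a=a,
                                        z=[rng.uniform(-1, 1)]))
            else:  # responds immediately, state-2 time varies
                t2 = 2.5 if long_stay else 0.01
                recs.append(make_record(
                    [(0.0, 1), (0.005, 2), (0.005 + t2, 3)], 0.005 + t2, 1,
                    a=a, z=[rng.uniform(-1, 1)]))
        data = TrialDataset(recs, tau=3.0, n_states=3)
        pi = estimate_propensity(data)
        w1 = PreferenceWeight((1.0, 0.0, 0.0))
        w2 = PreferenceWeight((0.0, 1.0, 0.0))
        omega = covariance_matrix(data, [(1, w1), (1, w2)], NO_CENS, pi)
        corr = omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
        assert abs(corr) < 0.15


class TestSimultaneousBand:
    def test_single_component_matches_normal_quantile(self):
        band = simultaneous_band([0.0], [[1.0]], n=100, alpha=0.05, B=100_000,
                                 seed=1)
        assert band.c_alpha == pytest.approx(norm.ppf(0.975), abs=0.02)

    def test_two_independent_components_match_sidak(self):
        band = simultaneous_band([0.0, 0.0], np.eye(2), n=100, alpha=0.05,
                                 B=100_000, seed=2)
        sidak = norm.ppf((1 + 0.95 ** 0.5) / 2)
        assert band.c_alpha == pytest.approx(sidak, abs=0.02)

    def test_perfectly_correlated_components_collapse(self):
        omega = np.ones((3, 3))
        band = simultaneous_band([0.0, 0.0, 0.0], omega, n=100, alpha=0.05,
                                 B=100_000, seed=3)
        assert band.c_alpha == pytest.approx(norm.ppf(0.975), abs=0.02)

    def test_simultaneous_dominates_pointwise(self, w_response):
        data = simulate_trial(SimScenario(1, -1.0, 150, seed=5))
        pi = estimate_propensity(data)
        h = nelson_aalen_censoring(data)
        w2 = PreferenceWeight((1.0, 1.0, 0.0))
        entries = [(1, w_response), (-1, w_response), (1, w2), (-1, w2)]
        est = [estimate_value(data, d, w, h, pi) for d, w in entries]
        omega = covariance_matrix(data, entries, h, pi)
        band = simultaneous_band(est, omega, n=len(data), B=2000, seed=6)
        assert band.c_alpha >= norm.ppf(0.975) - 0.05

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            simultaneous_band([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]], n=50)


class TestValueReport:
    def test_report_shape_and_contrast_consistency(self, w_response):
        data = simulate_trial(SimScenario(1, -1.0, 120, seed=8))
        pi = estimate_propensity(data)
        h = nelson_aalen_censoring(data)
        fit = fit_linear(data, w_response, 120**-0.5, h, pi)
        report = value_report(data, {w_response: fit.f}, B=500, seed=3)
        assert len(report) == 3
        v_d = report.loc[report.parameter == "V(d_hat)", "estimate"].iloc[0]
        diff_p = report.loc[
            report.parameter == "V(d_hat) - V(+1)", "estimate"
        ].iloc[0]
        v_plus = estimate_value(data, 1, w_response, h, pi)
        assert diff_p == pytest.approx(v_d - v_plus)
        # simultaneous intervals contain the pointwise ones
        assert (report.sim_ci_low <= report.ci_low + 1e-12).all()
        assert (report.sim_ci_high >= report.ci_high - 1e-12).all()
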