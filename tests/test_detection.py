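"""Detection-model likelihoods, their oracles, and the GOF test."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stripsurvey as ss
from stripsurvey.detection import removal_fi_loglik
from stripsurvey.errors import BoundaryError, NoInformationError

from conftest import make_distance_events, removal_events


def grid_mle_removal(n1, n2, step=1e-6):
    """Two-stage exhaustive grid maximiser of the removal conditional
    likelihood over p in (0, 1).  The log-likelihood has a single sign
    change in its derivative, so refining around the coarse argmax is
    exact at the final resolution."""
    coarse = np.arange(step * 1e3, 1.0, step * 1e3)
    ll = [removal_fi_loglik(p, n1, n2) for p in coarse]
    p_c = coarse[int(np.argmax(ll))]
    lo, hi = max(step, p_c - 2e-3), min(1.0 - step, p_c + 2e-3)
    fine = np.arange(lo, hi, step)
    ll = [removal_fi_loglik(p, n1, n2) for p in fine]
    return float(fine[int(np.argmax(ll))])


class TestRemovalFit:
    def test_perfect_first_observer(self):
        fit = ss.fit_removal_fi(removal_events(40, 0))
        assert fit.params["p"] == 1.0
        assert fit.P_hat == 1.0

    @pytest.mark.parametrize("n1,n2", [(40, 10), (13, 4), (100, 99), (7, 1)])
    def test_matches_grid_search_oracle(self, n1, n2):
        fit = ss.fit_removal_fi(removal_events(n1, n2))
        assert fit.params["p"] == pytest.approx(grid_mle_removal(n1, n2), abs=2e-6)
        assert fit.P_hat == pytest.approx(1 - (1 - fit.params["p"]) ** 2, abs=1e-12)

    def test_combined_at_least_single(self):
        fit = ss.fit_removal_fi(removal_events(40, 10))
        assert fit.P_hat >= fit.params["p"]

    def test_boundary_and_no_information_errors(self):
        with pytest.raises(NoInformationError):
            ss.fit_removal_fi(removal_events(0, 3))
        with pytest.raises(BoundaryError):
            ss.fit_removal_fi(removal_events(5, 5))
        with pytest.raises(BoundaryError):
            ss.fit_removal_fi(removal_events(5, 9))

    def test_se_matches_numerical_information(self):
        n1, n2 = 40, 10
        fit = ss.fit_removal_fi(removal_events(n1, n2))
        p = fit.params["p"]
        h = 1e-5
        d2 = (
            removal_fi_loglik(p + h, n1, n2)
            - 2 * removal_fi_loglik(p, n1, n2)
            + removal_fi_loglik(p - h, n1, n2)
        ) / h**2
        se_p = 1.0 / math.sqrt(-d2)
        assert math.sqrt(fit.vcov[0, 0]) == pytest.approx(se_p, rel=1e-4)
        assert fit.se_P == pytest.approx(2 * (1 - p) * se_p, rel=1e-4)

    def test_P_increases_in_p(self):
        fits = [ss.fit_removal_fi(removal_events(40, n2)) for n2 in (30, 20, 10, 1)]
        P = [f.P_hat for f in fits]
        assert P == sorted(P)


class TestHalfNormal:
    def test_value_on_the_line_is_p0(self):
        assert ss.halfnormal_g(0.0, 0.7, 0.4) == pytest.approx(0.7, abs=1e-15)

    def test_flat_limit(self):
        assert ss.halfnormal_g(1.0, 1.0, 1e9) == pytest.approx(1.0, abs=1e-9)

    def test_direct_evaluation(self):
        assert ss.halfnormal_g(0.5, 1.0, 0.5) == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )

    @pytest.mark.parametrize(
        "y,p0,sigma", [(-0.1, 0.5, 0.5), (0.1, 0.0, 0.5), (0.1, 1.2, 0.5),
                       (0.1, 0.5, 0.0)]
    )
    def test_domain_violations(self, y, p0, sigma):
        with pytest.raises(ValueError):
            ss.halfnormal_g(y, p0, sigma)


class TestAverageDetection:
    def test_perfect_detection_limit(self):
        assert ss.average_detection(1.0, 1e9, 1.0) == pytest.approx(1.0, abs=1e-8)

    def test_distance_free_case(self):
        # flat curve at p0 = 0.5: combined probability 1 - 0.25 = 0.75
        assert ss.average_detection(0.5, 1e9, 2.0) == pytest.approx(0.75, abs=1e-8)

    @pytest.mark.parametrize(
        "p0,sigma,w", [(0.8, 0.4, 1.0), (0.3, 0.15, 1.0), (0.95, 2.0, 0.5)]
    )
    def test_matches_trapezoid_oracle(self, p0, sigma, w):
        y = np.linspace(0.0, w, 10**6 + 1)
        g = p0 * np.exp(-(y**2) / (2 * sigma**2))
        oracle = np.trapezoid(1 - (1 - g) ** 2, y) / w
        assert ss.average_detection(p0, sigma, w) == pytest.approx(oracle, abs=1e-6)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        p0=st.floats(0.05, 1.0),
        sigma=st.floats(0.05, 5.0),
        w=st.floats(0.2, 3.0),
    )
    def test_monotone_in_p0_and_sigma(self, p0, sigma, w):
        base = ss.average_detection(p0, sigma, w)
        if p0 <= 0.99:
            assert ss.average_detection(min(1.0, p0 + 0.01), sigma, w) > base
        assert ss.average_detection(p0, sigma * 1.1, w) > base


class TestDistanceRemovalFit:
    def test_parameter_recovery(self, rng):
        events = make_distance_events(rng, 12000, p0=0.8, sigma=0.4)
        fit = ss.fit_distance_removal(events, 1.0)
        se_p0 = math.sqrt(fit.vcov[0, 0])
        se_sg = math.sqrt(fit.vcov[1, 1])
        assert abs(fit.params["p0"] - 0.8) < 3 * se_p0
        assert abs(fit.params["sigma"] - 0.4) < 3 * se_sg
        # P_hat consistent with the quadrature average at the optimum
        assert fit.P_hat == pytest.approx(
            ss.average_detection(fit.params["p0"], fit.params["sigma"], 1.0),
            abs=1e-9,
        )

    def test_loglik_at_optimum_beats_truth(self, rng):
        from stripsurvey.detection import _nll_distance
        from scipy.special import logit

        events = make_distance_events(rng, 2000, p0=0.7, sigma=0.5)
        fit = ss.fit_distance_removal(events, 1.0)
        y1 = np.array([e.distance_m for e in events
                       if e.history is ss.History.FIRST_OBSERVER])
        y2 = np.array([e.distance_m for e in events
                       if e.history is ss.History.SECOND_OBSERVER_ONLY])
        nll_truth = _nll_distance(
            np.array([logit(0.7), math.log(0.5)]), y1, y2, 0, 0, 1.0
        )
        assert fit.loglik >= -nll_truth - 1e-6

    def test_loglik_invariant_to_order_and_doubles_with_duplication(self, rng):
        events = make_distance_events(rng, 600, p0=0.8, sigma=0.4)
        fit = ss.fit_distance_removal(events, 1.0)
        rev = ss.fit_distance_removal(events[::-1], 1.0)
        assert rev.loglik == pytest.approx(fit.loglik, abs=1e-6)
        dup = ss.fit_distance_removal(events + events, 1.0)
        assert dup.loglik == pytest.approx(2 * fit.loglik, abs=1e-4)

    def test_all_first_observer_near_line_hits_p0_boundary_cleanly(self):
        events = [
            ss.DetectionEvent("d01", ss.History.FIRST_OBSERVER, 1, d)
            for d in (0.01, 0.02, 0.03, 0.05, 0.04, 0.02, 0.06, 0.01)
        ]
        fit = ss.fit_distance_removal(events, 1.0)
        assert fit.params["p0"] > 0.99
        assert np.isfinite(fit.loglik)

    def test_identical_distances_flag_rank_deficiency(self):
        events = removal_events(0, 0)
        events = [
            ss.DetectionEvent("d01", h, 1, 0.3)
            for h in [ss.History.FIRST_OBSERVER] * 8
            + [ss.History.SECOND_OBSERVER_ONLY] * 2
        ]
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            fit = ss.fit_distance_removal(events, 1.0)
        assert math.isnan(fit.se_P)

    def test_boundary_collapse_raises(self):
        """As many second-observer-only as first-observer events pushes
        p0 to the zero boundary, where the detection probability (and
        hence density) is undefined.  Synthetic dataset drawn from the
        simulator at p0=0.9, sigma=0.38."""
        dists = [0.567, 0.487, 0.446, 0.473, 0.233, 0.213, 0.903, 0.78,
                 0.51, 0.643, 0.058, 0.479, 0.728, 0.679, 0.377, 0.384,
                 0.249, 0.832]
        hist = "sfsffffsssssfssfff"
        events = [
            ss.DetectionEvent(
                "d01",
                ss.History.FIRST_OBSERVER if h == "f"
                else ss.History.SECOND_OBSERVER_ONLY,
                1, d,
            )
            for d, h in zip(dists, hist)
        ]
        with pytest.raises(BoundaryError):
            ss.fit_distance_removal(events, 1.0)

    def test_needs_three_distances(self):
        events = [ss.DetectionEvent("d01", ss.History.FIRST_OBSERVER, 1, 0.1)]
        with pytest.raises(NoInformationError):
            ss.fit_distance_removal(events, 1.0)

    def test_se_P_shrinks_with_sample_size(self):
        """Delta-method se_P decreases monotonically over n in
        {50, 200, 800}, averaged over replicates."""
        rng = np.random.default_rng(42)
        means = []
        for n_target in (50, 200, 800):
            ses = []
            reps = 0
            while reps < 40:
                events = make_distance_events(
                    rng, int(n_target / 0.56), p0=0.8, sigma=0.4
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        fit = ss.fit_distance_removal(events, 1.0)
                except BoundaryError:
                    continue
                if np.isfinite(fit.se_P):
                    ses.append(fit.se_P)
                reps += 1
            means.append(np.mean(ses))
        assert means[0] > means[1] > means[2]


class TestGof:
    @staticmethod
    def _fit(rng, n=700, p0=0.8, sigma=0.4):
        events = make_distance_events(rng, n, p0=p0, sigma=sigma)
        return ss.fit_distance_removal(events, 1.0), events

    def test_exact_agreement_gives_zero(self, rng):
        fit, events = self._fit(rng)
        # build synthetic "observations" exactly matching expectations
        res = ss.gof_chisq(fit, events, k=5)
        fake = ss.GofResult(
            chi2=0.0, k=5, df=res.df, p_value=1.0,
            observed=res.expected, expected=res.expected,
        )
        chi2 = float(np.sum((fake.observed - fake.expected) ** 2 / fake.expected))
        assert chi2 == 0.0
        assert stats.chi2.sf(chi2, res.df) == 1.0

    def test_published_arithmetic_with_df_override(self, rng):
        """The upper tail of chi-squared at 2.82 with df = 3 is 0.42 to
        two decimals (the df convention used in the published report)."""
        fit, events = self._fit(rng)
        res = ss.gof_chisq(fit, events, k=3, df=3)
        assert stats.chi2.sf(2.82, res.df) == pytest.approx(0.42, abs=0.005)

    def test_df_default_and_errors(self, rng):
        fit, events = self._fit(rng)
        assert ss.gof_chisq(fit, events, k=6).df == 3
        with pytest.raises(ValueError):
            ss.gof_chisq(fit, events, k=3)  # df = 0
        with pytest.raises(ValueError):
            ss.gof_chisq(fit, events, k=1)

    def test_small_expected_counts_warn(self, rng):
        fit, events = self._fit(rng, n=30, sigma=0.25)
        with pytest.warns(RuntimeWarning, match="fewer bins"):
            ss.gof_chisq(fit, events, k=25)

    def test_statistic_brackets_chisq_references(self):
        """Under the fitted model the binned statistic with an unbinned
        MLE is stochastically between chi2_{k-1-npar} and chi2_{k-1}:
        rejection is anticonservative at df = k-1-npar and conservative
        at df = k-1 (checked over 250 refitted replicates)."""
        rng = np.random.default_rng(7)
        p_low, p_high = [], []
        for _ in range(250):
            events = make_distance_events(rng, 700, p0=0.8, sigma=0.4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = ss.fit_distance_removal(events, 1.0)
            p_low.append(ss.gof_chisq(fit, events, k=6).p_value)
            p_high.append(ss.gof_chisq(fit, events, k=6, df=5).p_value)
        p_low, p_high = np.asarray(p_low), np.asarray(p_high)
        assert np.mean(p_low < 0.05) >= 0.05 - 0.02
        assert np.mean(p_high < 0.05) <= 0.05 + 0.02
        # p-values are not degenerate under either convention
        assert 0.2 < p_low.mean() < 0.55
        assert 0.45 < p_high.mean() < 0.8
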