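"""Transforms, Scheffé OLS fits, adequacy statistics and hold-out checks."""

import numpy as np
import pytest

import lipidmix as lm
from lipidmix.exceptions import (
    DomainError,
    PredictionDomainError,
    SingularInformationError,
    UnderDeterminedError,
    ValidationLeakageError,
)
from tests.conftest import random_mixture_design


class TestNormalizeMFI:
    def test_identity_and_scaling(self):
        assert lm.normalize_mfi(100.0, 100.0) == 1.0
        # the Spikevax-ratio control lands around 2.2-fold over background
        assert lm.normalize_mfi(2.2 * 340.0, 340.0) == pytest.approx(2.2)

    def test_zero_control_rejected(self):
        with pytest.raises(DomainError):
            lm.normalize_mfi(10.0, 0.0)


class TestPowerTransform:
    @pytest.mark.parametrize("lam", [-2.0, -1.5, -0.5, 0.0, 0.5, 1.0, 2.0])
    def test_round_trip(self, lam, rng):
        y = rng.uniform(0.2, 50.0, size=40)
        t = lm.power_transform(y, lam)
        np.testing.assert_allclose(lm.inverse_power(t, lam), y, rtol=1e-10)

    def test_hand_values(self):
        assert lm.power_transform(np.array([4.0]), 0.5)[0] == 2.0
        assert lm.power_transform(np.array([3.0]), 1.0)[0] == 3.0
        # inverse of the nMFI transform: t^(-2/3)
        y = lm.inverse_power(np.array([0.456695]), -1.5)[0]
        assert y == pytest.approx(0.456695 ** (-2 / 3))
        assert y == pytest.approx(1.687, abs=2e-3)

    def test_negative_exponent_is_decreasing(self):
        y = np.array([1.0, 2.0, 5.0])
        t = lm.power_transform(y, -1.5)
        assert np.all(np.diff(t) < 0)

    def test_domain_guards(self):
        with pytest.raises(DomainError):
            lm.power_transform(np.array([0.0, 1.0]), 0.0)
        with pytest.raises(DomainError):
            lm.inverse_power(np.array([-1.0]), -1.5)


class TestBoxCoxScan:
    def _sim(self, lam, rng, sigma=0.05):
        d = random_mixture_design(rng, 30, 3)
        spec = lm.ModelSpec.linear(3)
        beta = np.array([2.0, 4.0, 7.0])
        x = spec.matrix(d.compositions)
        t = x @ beta + rng.normal(0, sigma, 30)
        y = lm.inverse_power(t, lam) if lam != 0 else np.exp(t)
        return y, x

    @pytest.mark.parametrize("lam,sigma", [(1.0, 0.05), (0.0, 0.2)])
    def test_generating_exponent_usually_in_ci(self, lam, sigma, rng):
        """The ~95% profile CI covers the generating exponent most of the time."""
        hits = 0
        for _ in range(40):
            y, x = self._sim(lam, rng, sigma)
            scan = lm.boxcox_scan(y, x)
            hits += scan.ci_lower <= lam <= scan.ci_upper
        assert hits >= 30

    def test_scale_invariance_of_profile_shape(self, rng):
        """Rescaling y shifts the profile by a constant when X spans 1."""
        y, x = self._sim(0.5, rng)
        s1 = lm.boxcox_scan(y, x)
        s2 = lm.boxcox_scan(y * 137.2, x)
        np.testing.assert_allclose(
            s1.loglik - s1.loglik.max(), s2.loglik - s2.loglik.max(), atol=1e-7
        )
        assert s1.best_lambda == s2.best_lambda
        assert (s1.ci_lower, s1.ci_upper) == (s2.ci_lower, s2.ci_upper)

    def test_positivity_required(self, rng):
        with pytest.raises(DomainError):
            lm.boxcox_scan(np.array([1.0, -2.0, 3.0]), np.ones((3, 1)))

    def test_narrow_grid_rejected(self, rng):
        y, x = self._sim(1.0, rng)
        with pytest.raises(ValueError):
            lm.boxcox_scan(y, x, lambdas=np.linspace(-1, 1, 20))


class TestChooseConvenientLambda:
    def _scan(self, best, lo, hi):
        return lm.models.BoxCoxScan(
            lambdas=np.linspace(-3, 3, 121),
            loglik=np.zeros(121),
            best_lambda=best,
            ci_lower=lo,
            ci_upper=hi,
        )

    @pytest.mark.parametrize(
        "best,lo,hi,expected",
        [
            (0.93, 0.6, 1.3, 1.0),
            (-1.4, -1.9, -0.9, -1.5),
            (0.45, 0.3, 0.7, 0.5),
        ],
    )
    def test_nearest_convenient_in_ci(self, best, lo, hi, expected):
        assert lm.choose_convenient_lambda(self._scan(best, lo, hi)).lam == expected

    def test_warns_when_ci_misses_all(self):
        with pytest.warns(UserWarning):
            spec = lm.choose_convenient_lambda(self._scan(0.27, 0.2, 0.3))
        assert spec.lam == 0.5


class TestScheffeMatrix:
    def test_row_with_interaction(self):
        spec = lm.ModelSpec(((0,), (1,), (0, 1)), 2)
        row = lm.scheffe_matrix(np.array([[0.5, 0.5]]), spec)
        np.testing.assert_allclose(row, [[0.5, 0.5, 0.25]])

    def test_linear_rows_sum_to_one(self, design16):
        x = lm.scheffe_matrix(design16, lm.ModelSpec.linear(4))
        np.testing.assert_allclose(x.sum(axis=1), 1.0, atol=1e-12)

    def test_ms_interaction_column(self, design16):
        spec = lm.ModelSpec(((0, 2),), 4)
        ms = design16.validation_rows()
        assert lm.scheffe_matrix(ms, spec)[0, 0] == pytest.approx(0.10 * 0.385)


class TestFitScheffe:
    def test_exact_recovery_all_builtin_models(self, design16, truths):
        """Noiseless synthetic data reproduce generating coefficients."""
        sim = lm.simulate_responses(
            design16,
            {k: lm.GroundTruth(t.response, t.spec, t.coef, t.transform, 0.0)
             for k, t in truths.items()},
            seed=0,
        )
        for name, truth in truths.items():
            m = lm.fit_scheffe(design16, sim[name].to_numpy(), truth.spec, truth.transform)
            np.testing.assert_allclose(m.coef, truth.coef, rtol=1e-9)

    def test_holdout_rows_never_fitted(self, design16, truths):
        sim = lm.simulate_responses(design16, seed=3)
        t = truths["encapsulation_pct"]
        m = lm.fit_scheffe(design16, sim["encapsulation_pct"].to_numpy(), t.spec, t.transform)
        assert m.n == 15 and "MS" not in m.run_ids

    def test_hat_and_orthogonality_invariants(self, design16, truths):
        sim = lm.simulate_responses(design16, seed=5)
        t = truths["diameter_nm"]
        m = lm.fit_scheffe(design16, sim["diameter_nm"].to_numpy(), t.spec, t.transform)
        assert m.hat.sum() == pytest.approx(m.p, abs=1e-8)
        assert np.all((m.hat >= -1e-12) & (m.hat <= 1 + 1e-12))
        x = t.spec.matrix(design16.modeling_rows().compositions)
        np.testing.assert_allclose(x.T @ m.residuals, 0.0, atol=1e-8)

    def test_unbiased_coefficients_under_noise(self, design16, truths):
        """Mean OLS estimates across refits sit within Monte-Carlo error."""
        t = truths["encapsulation_pct"]
        n_seeds = 300
        sims = lm.simulate_responses(
            design16, {t.response: t}, seed=2024, n_rep=n_seeds, truncate=False
        )
        coefs = np.array([
            lm.fit_scheffe(design16, s[t.response].to_numpy(), t.spec, t.transform).coef
            for s in sims
        ])
        se = coefs.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        # 4 coefficients tested jointly: allow 3.5 MC standard errors each
        assert np.all(np.abs(coefs.mean(axis=0) - t.coef) < 3.5 * se)

    def test_duplicate_terms_rejected_at_spec(self):
        with pytest.raises(ValueError):
            lm.ModelSpec(((0,), (1,), (0, 1), (1, 0)), 2)

    def test_rank_deficient_design_singular(self):
        # five copies of one blend: rank-1 model matrix for a 3-term model
        d = lm.Design(np.tile([0.4, 0.6], (5, 1)), ("a", "b"))
        with pytest.raises(SingularInformationError):
            lm.fit_scheffe(d, np.arange(1.0, 6.0), lm.ModelSpec.quadratic(2))

    def test_underdetermined(self):
        d = lm.Design(np.array([[0.5, 0.5], [0.3, 0.7]]), ("a", "b"))
        with pytest.raises(UnderDeterminedError):
            lm.fit_scheffe(d, np.array([1.0, 2.0]), lm.ModelSpec.quadratic(2))


class TestFitStatistics:
    def test_perfect_fit(self, design16, truths):
        t = truths["nmfi"]
        sim = lm.simulate_responses(
            design16,
            {t.response: lm.GroundTruth(t.response, t.spec, t.coef, t.transform, 0.0)},
            seed=0,
        )
        m = lm.fit_scheffe(design16, sim[t.response].to_numpy(), t.spec, t.transform)
        s = lm.fit_statistics(m)
        assert s.r2 == pytest.approx(1.0, abs=1e-12)
        assert s.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert s.pred_r2 == pytest.approx(1.0, abs=1e-9)
        assert s.press == pytest.approx(0.0, abs=1e-18)

    def test_press_equals_explicit_loo(self, rng):
        """The e/(1-h) shortcut reproduces brute-force leave-one-out."""
        for _ in range(5):
            d = random_mixture_design(rng, 12, 3)
            spec = lm.ModelSpec.quadratic(3)
            y = rng.uniform(1.0, 10.0, 12)
            m = lm.fit_scheffe(d, y, spec)
            press = 0.0
            x = spec.matrix(d.compositions)
            for i in range(12):
                mask = np.arange(12) != i
                beta, *_ = np.linalg.lstsq(x[mask], y[mask], rcond=None)
                press += (y[i] - x[i] @ beta) ** 2
            assert lm.fit_statistics(m).press == pytest.approx(press, rel=1e-10)

    def test_ordering_invariants(self, design16, truths, rng):
        sims = lm.simulate_responses(design16, seed=77, n_rep=10)
        for sim in sims:
            for name, t in truths.items():
                m = lm.fit_scheffe(design16, sim[name].to_numpy(), t.spec, t.transform)
                s = lm.fit_statistics(m)
                assert s.adj_r2 <= s.r2 <= 1.0
                assert s.press >= m.sse - 1e-12


class TestAdequacy:
    def test_published_gaps_pass(self):
        """adj R2 - pred R2 gaps of the published fits are 0.08/0.09/0.04."""
        for name, row in lm.datasets.REPORTED_FIT_STATS.items():
            gap = row["adj_r2"] - row["pred_r2"]
            assert gap < 0.2
        stats = lm.FitStats(
            std_dev=14.31, mean=59.49, cv_pct=24.06, r2=0.6273,
            adj_r2=0.5987, press=np.nan, pred_r2=0.5139,
            adequate_precision=16.84,
        )
        flags = lm.adequacy_check(stats)
        assert flags.r2_gap_ok and flags.adequate_precision_ok and flags.passed

    def test_overfit_flagged(self):
        stats = lm.FitStats(1, 1, 1, 0.95, 0.9, 1.0, 0.6, 10.0)
        assert not lm.adequacy_check(stats).r2_gap_ok

    def test_low_precision_flagged(self):
        stats = lm.FitStats(1, 1, 1, 0.9, 0.85, 1.0, 0.8, 3.9)
        assert not lm.adequacy_check(stats).adequate_precision_ok


class TestPredict:
    def _fitted_truth(self, design16, truth):
        sim = lm.simulate_responses(
            design16,
            {truth.response: lm.GroundTruth(
                truth.response, truth.spec, truth.coef, truth.transform, 0.0)},
            seed=0,
        )
        return lm.fit_scheffe(
            design16, sim[truth.response].to_numpy(), truth.spec, truth.transform
        )

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("encapsulation_pct", 75.08),
            ("diameter_nm", 99.4),
            ("nmfi", 1.69),
        ],
    )
    def test_spikevax_ratio_predictions(self, design16, truths, name, expected):
        """Predictions at the commercial 10/50/38.5/1.5 composition."""
        m = self._fitted_truth(design16, truths[name])
        pred = lm.predict_response(m, design16.validation_rows())[0]
        assert pred == pytest.approx(expected, rel=5e-3)

    def test_negative_lambda_out_of_domain(self, design16, truths):
        m = self._fitted_truth(design16, truths["nmfi"])
        # force a composition where the transformed prediction goes negative
        m2 = lm.FittedModel(
            spec=m.spec, transform=m.transform, coef=-np.abs(m.coef),
            fitted=m.fitted, residuals=m.residuals, hat=m.hat, sse=m.sse,
            n=m.n, p=m.p, run_ids=m.run_ids,
        )
        with pytest.raises(PredictionDomainError):
            lm.predict_response(m2, np.array([[0.25, 0.25, 0.25, 0.25]]))


class TestHoldout:
    def test_leakage_refused(self, design16, truths):
        t = truths["encapsulation_pct"]
        sim = lm.simulate_responses(design16, seed=9)
        m = lm.fit_scheffe(design16, sim[t.response].to_numpy(), t.spec, t.transform)
        with pytest.raises(ValidationLeakageError):
            lm.holdout_validation(m, design16.modeling_rows(), np.ones(15))

    def test_noiseless_holdout_has_zero_error(self, design16, truths):
        t = truths["encapsulation_pct"]
        truth0 = lm.GroundTruth(t.response, t.spec, t.coef, t.transform, 0.0)
        sim = lm.simulate_responses(design16, {t.response: truth0}, seed=0)
        m = lm.fit_scheffe(design16, sim[t.response].to_numpy(), t.spec, t.transform)
        ms = design16.validation_rows()
        y_ms = sim.set_index("run_id").loc["MS", t.response]
        table = lm.holdout_validation(m, ms, np.array([y_ms]))
        assert len(table) == 1
        assert table["rel_error"].iloc[0] == pytest.approx(0.0, abs=1e-10)
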