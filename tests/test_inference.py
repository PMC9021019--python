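"""Likelihood fitting: composite log-likelihood, parameter recovery,
profile intervals and model comparison."""

import numpy as np
import pytest
from scipy.stats import norm

from contactburst.inference import (ApparentModel, FishDataset, FishLine,
                                    PhenomModel, ScreenDataset,
                                    composite_loglik, fit_apparent,
                                    fit_phenomenological, fit_variant,
                                    lrt_compare, predict_weak_enhancer,
                                    profile_ci)
from contactburst.synthetic import (StudyConfig, gen_full_study,
                                    DEFAULT_APPARENT_TRUTH)
from contactburst.telegraph import telegraph_pmf_closed_form
from contactburst.params import TelegraphParams

MODEL = PhenomModel(kon0=0.5, kon1=2.0, k_off=1.0, mu=10.0, c=0.5, h=2.0)


def _screen(p_c, means, sds=None, n_rep=3):
    p_c = np.asarray(p_c, float)
    means = np.asarray(means, float)
    sds = np.zeros_like(means) if sds is None else np.asarray(sds, float)
    n = p_c.size
    return ScreenDataset([f"L{i}" for i in range(n)], np.arange(n) * 1000,
                         ["+"] * n, p_c, means, sds,
                         np.full(n, n_rep))


class TestCompositeLoglik:
    def test_hand_computed_toy(self):
        """Two screen lines plus one five-cell histogram, against an
        independent arithmetic path (per-line Gaussian densities plus
        closed-form beta-Poisson log-probabilities)."""
        p = np.array([0.3, 0.8])
        model_mean = np.asarray(MODEL.mean(p))
        screen = _screen(p, [3.0, 6.0], sds=[0.6, 0.9], n_rep=3)
        hist = np.zeros(8)
        hist[[1, 3, 4]] = [2, 2, 1]       # 5 cells
        fish = FishDataset([FishLine("F0", 0.5, hist)])
        parts = composite_loglik(MODEL, screen, fish,
                                 error_model="per_line")
        se = np.array([0.6, 0.9]) / np.sqrt(3)
        expected_gauss = (norm.logpdf(3.0, model_mean[0], se[0])
                          + norm.logpdf(6.0, model_mean[1], se[1]))
        kon_mid = 0.5 + 1.5 * 0.5 ** 2 / (0.5 ** 2 + 0.5 ** 2)
        pmf = telegraph_pmf_closed_form(
            TelegraphParams(kon_mid, 1.0, 10.0), 7)
        expected_multi = (2 * np.log(pmf[1]) + 2 * np.log(pmf[3])
                          + np.log(pmf[4]))
        assert parts.gaussian == pytest.approx(expected_gauss, rel=1e-9)
        assert parts.multinomial == pytest.approx(expected_multi, rel=1e-9)
        assert parts.total == pytest.approx(
            expected_gauss + expected_multi, rel=1e-9)

    def test_empty_fish_reduces_to_gaussian(self):
        screen = _screen([0.2, 0.9], [2.0, 7.0], sds=[0.5, 0.5])
        parts = composite_loglik(MODEL, screen, FishDataset([]))
        assert parts.multinomial == 0.0
        assert parts.total == parts.gaussian

    def test_perfect_fit_maximizes_likelihood(self):
        """Histogram proportional to the model pmf and means on the model
        curve: the likelihood at the generating model beats perturbed
        models."""
        p = np.linspace(0.1, 1, 6)
        screen = _screen(p, np.asarray(MODEL.mean(p)), sds=np.full(6, 0.3))
        pmf = MODEL.pmf(0.5)
        fish = FishDataset([FishLine("F", 0.5, pmf * 1000)])
        ll0 = composite_loglik(MODEL, screen, fish).total
        for factor in (0.8, 1.25):
            worse = PhenomModel(0.5, 2.0 * factor, 1.0, 10.0 * factor,
                                0.5, 2.0)
            assert composite_loglik(worse, screen, fish).total < ll0

    def test_fish_weight_scales_multinomial_term(self):
        screen = _screen([0.5], [4.0], sds=[0.4])
        fish = FishDataset([FishLine("F", 0.5, MODEL.pmf(0.5) * 100)])
        p1 = composite_loglik(MODEL, screen, fish, fish_weight=1.0)
        p2 = composite_loglik(MODEL, screen, fish, fish_weight=0.5)
        assert p2.total == pytest.approx(
            p1.gaussian + 0.5 * p1.multinomial)


class TestPhenomenologicalFit:
    def test_noiseless_recovery_within_one_percent(self):
        truth = PhenomModel(kon0=0.05, kon1=2.0, k_off=1.5, mu=40.0,
                            c=0.15, h=2.8)
        p = np.linspace(0.02, 1, 50)
        screen = _screen(p, np.asarray(truth.mean(p)))
        fish = FishDataset([
            FishLine(f"F{i}", float(q), truth.pmf(q) * 500)
            for i, q in enumerate([0.05, 0.1, 0.2, 0.4, 0.7, 1.0])])
        fit = fit_phenomenological(screen, fish, n_starts=8, seed=1)
        for key, val in (("h", 2.8), ("c", 0.15), ("mu", 40.0),
                         ("k_off", 1.5), ("kon1", 2.0)):
            assert fit.params[key] == pytest.approx(val, rel=0.01), key

    def test_deterministic_given_seed(self, small_phenom_study):
        b = small_phenom_study
        f1 = fit_phenomenological(b.screen, b.fish, n_starts=4, seed=3)
        f2 = fit_phenomenological(b.screen, b.fish, n_starts=4, seed=3)
        assert f1.loglik == f2.loglik
        assert f1.params == f2.params

    def test_flat_response_flags_h_unidentifiable(self):
        flat = PhenomModel(kon0=1.0, kon1=1.0, k_off=1.5, mu=30.0,
                           c=0.3, h=2.0)
        p = np.linspace(0.05, 1, 30)
        screen = _screen(p, np.asarray(flat.mean(p)))
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_phenomenological(screen, FishDataset([]),
                                       n_starts=6, seed=0)
        assert fit.extras["h_identifiable"] is False


class TestApparentFit:
    def test_noiseless_recovery_of_step_count(self):
        truth = ApparentModel(**DEFAULT_APPARENT_TRUTH)
        p = np.linspace(0.02, 1, 50)
        screen = _screen(p, np.asarray(truth.mean(p)))
        fish = FishDataset([
            FishLine(f"F{i}", float(q), truth.pmf(q) * 500)
            for i, q in enumerate([0.05, 0.2, 0.5, 1.0])])
        fit = fit_apparent(screen, fish, n_grid=range(1, 9), n_starts=4,
                           seed=1)
        assert fit.params["n"] == 5
        assert fit.params["beta"] == pytest.approx(4.0, rel=0.05)

    def test_restricted_grid_is_nested(self):
        truth = ApparentModel(**DEFAULT_APPARENT_TRUTH)
        p = np.linspace(0.02, 1, 30)
        screen = _screen(p, np.asarray(truth.mean(p)))
        full = fit_apparent(screen, None, n_grid=[5], n_starts=4, seed=0)
        restricted = fit_apparent(screen, None, n_grid=[1], n_starts=4,
                                  seed=0)
        assert restricted.loglik < full.loglik - 1.0

    def test_per_n_profile_retained(self, small_apparent_study):
        b = small_apparent_study
        fit = fit_apparent(b.screen, b.fish, n_grid=range(3, 8),
                           n_starts=3, seed=0)
        assert set(fit.extras["n_profile"]) == set(range(3, 8))
        lo, hi = profile_ci(fit, "n", b.screen, b.fish)
        assert lo <= fit.params["n"] <= hi


class TestProfileCi:
    def test_quadratic_loglik_matches_wald_interval(self):
        """A pure Gaussian-mean problem has a quadratic log-likelihood:
        the profile interval must coincide with +-1.96 s.e."""
        rng = np.random.default_rng(0)
        p = np.full(40, 1.0)                 # saturated: mean = mu*k/(k+koff)
        truth = PhenomModel(0.5, 0.5, 1.0, 20.0, 0.5, 2.0)
        sigma = 0.5
        means = np.asarray(truth.mean(p)) + rng.normal(0, sigma, p.size)
        screen = _screen(p, means, sds=np.full(p.size, sigma * np.sqrt(3)))
        # only mu free: everything else fixed at truth
        from contactburst.inference import _neg_loglik_factory, FitResult
        build, neg_ll = _neg_loglik_factory(
            "phenomenological", ("mu",),
            {"kon0": 0.5, "kon1": 0.5, "k_off": 1.0, "c": 0.5, "h": 2.0},
            screen, None, 1.0, "per_line")
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda v: neg_ll([v]),
                              bounds=np.log([5, 100]), method="bounded")
        mu_hat = float(np.exp(res.x))
        fit = FitResult("phenomenological",
                        {"kon0": 0.5, "kon1": 0.5, "k_off": 1.0,
                         "c": 0.5, "h": 2.0, "mu": mu_hat},
                        ("mu",), -res.fun, True, 1, 0,
                        extras={"error_model": "per_line"})
        lo, hi = profile_ci(fit, "mu", screen, None)
        # Wald s.e. of mu: mean = mu * 1/3 here (k=0.5, koff=1.0),
        # se(mean) = sigma*sqrt(3)/sqrt(3)/sqrt(n) per-line -> analytic
        se_mu = 3 * sigma / np.sqrt(p.size)
        assert lo == pytest.approx(mu_hat - 1.96 * se_mu, rel=0.02)
        assert hi == pytest.approx(mu_hat + 1.96 * se_mu, rel=0.02)

    def test_bounded_profile_warns_half_open(self):
        truth = PhenomModel(0.5, 0.5, 1.0, 20.0, 0.5, 2.0)
        p = np.linspace(0.1, 1, 10)
        screen = _screen(p, np.asarray(truth.mean(p)),
                         sds=np.full(10, 10.0))   # nearly no information
        fit = fit_phenomenological(screen, FishDataset([]), n_starts=4,
                                   seed=0)
        with pytest.warns(UserWarning, match="half-open"):
            lo, hi = profile_ci(fit, "h", screen, None, max_steps=10)


@pytest.fixture(scope="module")
def truncated_study():
    truth = dict(DEFAULT_APPARENT_TRUTH)
    truth["kon_enh"] = truth["kon_enh"] / 2
    cfg = StudyConfig(seed=301, model="apparent", truth=truth,
                      n_lines=74, fish_lines=0)
    return gen_full_study(cfg)


class TestVariantComparison:
    def test_variant_identical_to_reference_has_p_one(self, truncated_study):
        b = truncated_study
        full = dict(DEFAULT_APPARENT_TRUTH)
        ref = fit_variant(b.screen, None, full, "all_free", n_starts=6,
                          seed=0)
        table = lrt_compare(ref, [ref])
        assert table["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert table["p_value"].iloc[0] > 0.99

    def test_kon_enh_only_variant_selected(self, truncated_study):
        b = truncated_study
        full = dict(DEFAULT_APPARENT_TRUTH)
        fits = {v: fit_variant(b.screen, None, full, v, n_starts=6, seed=0)
                for v in ("beta_only", "kon_enh_only", "both", "all_free")}
        table = lrt_compare(fits["all_free"],
                            [fits[v] for v in ("beta_only", "kon_enh_only",
                                               "both")])
        assert table.attrs["selected"] == "kon_enh_only"
        fold = full["kon_enh"] / fits["kon_enh_only"].params["kon_enh"]
        assert fold == pytest.approx(2.0, rel=0.15)

    def test_optimizer_failure_detected(self, truncated_study):
        b = truncated_study
        full = dict(DEFAULT_APPARENT_TRUTH)
        good = fit_variant(b.screen, None, full, "kon_enh_only",
                           n_starts=6, seed=0)
        bad_ref = fit_variant(b.screen, None, full, "all_free",
                              n_starts=6, seed=0)
        bad_ref.loglik = good.loglik - 5.0     # simulate a failed reference
        with pytest.raises(RuntimeError):
            lrt_compare(bad_ref, [good])


class TestNestingMonotonicity:
    def test_freeing_a_parameter_never_hurts(self, small_apparent_study):
        b = small_apparent_study
        full = dict(DEFAULT_APPARENT_TRUTH)
        lls = {v: fit_variant(b.screen, None, full, v, n_starts=6,
                              seed=0).loglik
               for v in ("beta_only", "both", "all_free")}
        assert lls["both"] >= lls["beta_only"] - 1e-6
        assert lls["all_free"] >= lls["both"] - 1e-6


class TestWeakEnhancerPrediction:
    FIT = ApparentModel(**DEFAULT_APPARENT_TRUTH)

    def test_factor_one_is_identity(self):
        p, curve = predict_weak_enhancer(self.FIT, "scale_kon_enh", 1.0)
        assert np.allclose(curve, np.asarray(self.FIT.mean(p)))

    def test_kon_enh_scaling_preserves_response_shape(self):
        """With a negligible basal rate, halving kon_enh scales k_on(p),
        and for k_on << k_off the mean scales by nearly the same factor
        at every contact probability."""
        model = ApparentModel(kon_basal=1e-6, kon_enh=0.2, beta=4.0, n=5,
                              k_off=10.0, mu=40.0)
        p = np.linspace(0.05, 1, 30)
        _, full = predict_weak_enhancer(model, "scale_kon_enh", 1.0, p)
        _, half = predict_weak_enhancer(model, "scale_kon_enh", 0.5, p)
        ratio = half / full
        assert np.allclose(ratio, ratio[0], rtol=0.02)

    def test_beta_scaling_shifts_half_maximum(self):
        p = np.linspace(0.001, 1, 2000)
        _, full = predict_weak_enhancer(self.FIT, "scale_beta", 1.0, p)
        _, weak = predict_weak_enhancer(self.FIT, "scale_beta", 0.5, p)

        def half_max_p(curve):
            target = curve[0] + (curve[-1] - curve[0]) / 2
            return p[np.argmin(np.abs(curve - target))]

        assert half_max_p(weak) > half_max_p(full)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            predict_weak_enhancer(self.FIT, "scale_kon_enh", 0.0)
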