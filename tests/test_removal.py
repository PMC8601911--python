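"""Removal N-mixture model: likelihood, fitting, GOF, prediction, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grassnet.config import TrueParameters
from grassnet.errors import ConfigurationError, NumericError
from grassnet.removal import (
    FittedModel,
    ModelSpec,
    RemovalCounts,
    auc_holdout,
    covariate_effect_size,
    crossval_holdout,
    fit,
    gof_parametric_bootstrap,
    marginal_neg_loglik,
    overdispersion_adjust,
    predict_expected_density,
    removal_cell_probs,
    residual_moran_correlogram,
    spearman_obs_pred,
)

from .conftest import RECOVERY_TRUTH, simulate_dataset
from .oracles import brute_force_neg_loglik


def _one_site(y, jdate=0.0):
    return RemovalCounts(
        counts=np.asarray([y]), covariates=pd.DataFrame(index=[0]), jdate=np.array([jdate])
    )


def _intercept_spec(offset=1.0, j=5):
    return ModelSpec(abundance_covariates=(), offset_area_km2=offset, j_intervals=j)


class TestRemovalCellProbs:
    def test_certain_detection(self):
        np.testing.assert_array_equal(removal_cell_probs(1.0, 5), [1, 0, 0, 0, 0, 0])

    def test_geometric_halving(self):
        expect = [0.5, 0.25, 0.125, 0.0625, 0.03125, 0.03125]
        np.testing.assert_allclose(removal_cell_probs(0.5, 5), expect, rtol=0, atol=0)

    def test_closed_form_p03(self):
        expect = [0.3, 0.21, 0.147, 0.1029, 0.07203, 0.16807]
        np.testing.assert_allclose(removal_cell_probs(0.3, 5), expect, rtol=1e-12)

    def test_out_of_range_probability_raises(self):
        with pytest.raises(NumericError):
            removal_cell_probs(1.2, 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        j=st.integers(min_value=1, max_value=8),
    )
    def test_probabilities_partition(self, p, j):
        probs = removal_cell_probs(p, j)
        assert (probs >= 0).all()
        assert abs(probs.sum() - 1.0) < 1e-12
        # removal counts can only decay (in expectation) across intervals
        assert (np.diff(probs[:j]) <= 1e-15).all()


class TestMarginalNegLoglik:
    def test_all_zero_counts_near_certain_detection(self):
        # p → 1: the only way to observe nothing is N = 0, probability e^{−λA}
        lam_a = 2.7
        data = _one_site([0, 0, 0, 0, 0])
        nll = marginal_neg_loglik([np.log(lam_a), 40.0, 0.0], data, _intercept_spec())
        assert nll == pytest.approx(lam_a, rel=1e-12)

    @pytest.mark.parametrize("lam_a,p", [(2.0, 0.5), (0.5, 0.2), (5.0, 0.9)])
    def test_matches_truncated_latent_sum(self, lam_a, p):
        y = [1, 1, 0, 0, 0]
        data = _one_site(y)
        params = [np.log(lam_a), np.log(p / (1 - p)), 0.0]
        closed = marginal_neg_loglik(params, data, _intercept_spec())
        brute = brute_force_neg_loglik(lam_a, p, y, k_max=500)
        assert closed == pytest.approx(brute, abs=1e-8)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        lam=st.floats(min_value=0.05, max_value=20.0),
        c=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_offset_identity(self, lam, c):
        """(λ, A) → (λ/c, cA) leaves the likelihood unchanged."""
        y = [2, 1, 0, 1, 0]
        data = _one_site(y)
        base = marginal_neg_loglik([np.log(lam), 0.3, 0.0], data, _intercept_spec(offset=1.0))
        scaled = marginal_neg_loglik(
            [np.log(lam / c), 0.3, 0.0], data, _intercept_spec(offset=c)
        )
        assert scaled == pytest.approx(base, rel=1e-10)

    def test_wrong_parameter_count_raises(self):
        with pytest.raises(ConfigurationError):
            marginal_neg_loglik([0.0], _one_site([0, 0, 0, 0, 0]), _intercept_spec())


class TestFit:
    def test_poisson_mle_with_certain_detection(self):
        """Intercept-only abundance, p fixed at 1: λ̂A is the mean total."""
        data = simulate_dataset(seed=10, n_sites=400)
        spec = _intercept_spec(offset=1.0)
        model = fit(data, spec, fix_detection=1.0)
        lam_hat = np.exp(model.beta_abund[0])
        assert lam_hat == pytest.approx(data.totals.mean(), rel=1e-6)

    def test_recovers_truth_roughly_on_one_dataset(self, default_spec):
        data = simulate_dataset(seed=11, n_sites=2000)
        model = fit(data, default_spec)
        assert model.converged
        truth = np.array(
            [RECOVERY_TRUTH.beta_abund["intercept"]]
            + [RECOVERY_TRUTH.beta_abund[c] for c in default_spec.abundance_covariates]
            + list(RECOVERY_TRUTH.beta_det)
        )
        assert np.all(np.abs(model.params - truth) <= 4 * model.se + 1e-3)

    def test_covariance_is_symmetric_psd(self, default_spec):
        data = simulate_dataset(seed=12, n_sites=500)
        model = fit(data, default_spec)
        np.testing.assert_allclose(model.cov, model.cov.T, atol=1e-10)
        assert (np.linalg.eigvalsh(model.cov) > 0).all()


class TestGOF:
    def test_nboot_zero_raises(self, default_spec):
        data = simulate_dataset(seed=13, n_sites=200)
        model = fit(data, default_spec)
        with pytest.raises(ConfigurationError):
            gof_parametric_bootstrap(model, data, nboot=0)

    def test_well_specified_c_hat_near_one(self, default_spec):
        data = simulate_dataset(seed=14, n_sites=300)
        model = fit(data, default_spec)
        gof = gof_parametric_bootstrap(model, data, nboot=30, seed=1)
        assert 0 <= gof.p_value <= 1
        assert 0.6 < gof.c_hat < 1.6  # single run; calibration study is separate

    def test_deterministic_given_seed(self, default_spec):
        data = simulate_dataset(seed=15, n_sites=200)
        model = fit(data, default_spec)
        a = gof_parametric_bootstrap(model, data, nboot=10, seed=5)
        b = gof_parametric_bootstrap(model, data, nboot=10, seed=5)
        np.testing.assert_array_equal(a.chi2_bootstrap, b.chi2_bootstrap)


class TestOverdispersionAdjust:
    @pytest.fixture()
    def model(self, default_spec):
        data = simulate_dataset(seed=16, n_sites=300)
        return fit(data, default_spec)

    def test_below_one_floored_ses_unchanged(self, model):
        adj = overdispersion_adjust(model, 0.7)
        assert adj.c_hat == 1.0
        np.testing.assert_array_equal(adj.se, model.se)

    def test_c_hat_four_doubles_ses(self, model):
        adj = overdispersion_adjust(model, 4.0)
        np.testing.assert_allclose(adj.se, 2 * model.se)
        np.testing.assert_array_equal(adj.params, model.params)

    def test_identity_at_one(self, model):
        adj = overdispersion_adjust(model, 1.0)
        np.testing.assert_array_equal(adj.se, model.se)

    def test_nonpositive_raises(self, model):
        with pytest.raises(NumericError):
            overdispersion_adjust(model, 0.0)


def _toy_model(beta0: float, var0: float) -> FittedModel:
    spec = _intercept_spec()
    cov = np.zeros((3, 3))
    cov[0, 0] = var0
    return FittedModel(
        params=np.array([beta0, 0.0, 0.0]), cov=cov, loglik=0.0,
        converged=True, spec=spec, n_sites=1,
    )


class TestPrediction:
    def test_zero_se_layers_identical(self):
        model = _toy_model(beta0=1.0, var0=0.0)
        point, minus, plus = predict_expected_density(model, pd.DataFrame(index=[0]))
        assert point[0] == minus[0] == plus[0] == pytest.approx(np.e)

    def test_intercept_shift_layers(self):
        """β₀ = 0, SE = 0.5 → layers (e^{−0.98}, 1, e^{0.98})."""
        model = _toy_model(beta0=0.0, var0=0.25)
        point, minus, plus = predict_expected_density(model, pd.DataFrame(index=[0]))
        assert point[0] == pytest.approx(1.0)
        assert minus[0] == pytest.approx(np.exp(-0.98))
        assert plus[0] == pytest.approx(np.exp(0.98))

    def test_all_means_gives_intercept_density(self, default_spec):
        data = simulate_dataset(seed=17, n_sites=400)
        model = fit(data, default_spec)
        at_means = pd.DataFrame(
            {c: [0.0] for c in default_spec.abundance_covariates}
        )
        point, _, _ = predict_expected_density(model, at_means)
        assert point[0] == pytest.approx(np.exp(model.beta_abund[0]))


class TestEffectSize:
    @pytest.fixture()
    def model(self, default_spec):
        data = simulate_dataset(seed=18, n_sites=500)
        return fit(data, default_spec)

    def test_ratio_is_exp_of_coefficient(self, model, default_spec):
        for i, name in enumerate(default_spec.abundance_covariates):
            eff = covariate_effect_size(model, name)
            assert eff["ratio"] == pytest.approx(np.exp(model.beta_abund[i + 1]))

    def test_exp_03_value(self):
        model = _toy_model(beta0=0.0, var0=0.0)
        spec = ModelSpec(abundance_covariates=("g",))
        model = FittedModel(
            params=np.array([0.0, 0.3, 0.0, 0.0]), cov=np.zeros((4, 4)),
            loglik=0.0, converged=True, spec=spec, n_sites=1,
        )
        assert covariate_effect_size(model, "g")["ratio"] == pytest.approx(1.3499, abs=1e-4)

    def test_unknown_covariate_raises(self, model):
        with pytest.raises(ConfigurationError):
            covariate_effect_size(model, "nonesuch")


class TestHoldoutValidation:
    def test_crossval_deterministic_and_sane(self, default_spec):
        data = simulate_dataset(seed=19, n_sites=400)
        a = crossval_holdout(data, default_spec, seed=3)
        b = crossval_holdout(data, default_spec, seed=3)
        assert a == b
        assert a["rmse"] >= a["mae"] > 0

    def test_bad_holdout_fraction_raises(self, default_spec):
        data = simulate_dataset(seed=19, n_sites=100)
        with pytest.raises(ConfigurationError):
            crossval_holdout(data, default_spec, holdout_frac=0.0)

    def test_auc_high_for_strongly_separated_truth(self):
        truth = TrueParameters(
            beta_abund={"intercept": 0.5, "grassland": 3.0, "agriculture": 0.0,
                        "forest": 0.0, "urban": 0.0, "tmax": 0.0, "prcp": 0.0},
            beta_det=(0.5, 0.0),
        )
        data = simulate_dataset(seed=20, n_sites=600, truth=truth, offset_area_km2=1.0)
        spec = ModelSpec(offset_area_km2=1.0)
        out = auc_holdout(data, spec, reps=5, seed=4)
        assert out["mean_auc"] > 0.9
        assert out["acceptable"]

    def test_auc_near_half_for_covariate_free_truth(self):
        truth = TrueParameters(
            beta_abund={"intercept": 0.0, "grassland": 0.0, "agriculture": 0.0,
                        "forest": 0.0, "urban": 0.0, "tmax": 0.0, "prcp": 0.0},
            beta_det=(0.5, 0.0),
        )
        data = simulate_dataset(seed=21, n_sites=2000, truth=truth, offset_area_km2=1.0)
        out = auc_holdout(data, ModelSpec(offset_area_km2=1.0), reps=10, seed=5)
        assert out["mean_auc"] == pytest.approx(0.5, abs=0.05)

    def test_spearman_positive_when_well_specified(self, default_spec):
        data = simulate_dataset(seed=22, n_sites=1000)
        model = fit(data, default_spec)
        assert spearman_obs_pred(model, data) > 0

    def test_spearman_nan_for_constant_predictions(self):
        data = simulate_dataset(seed=23, n_sites=200)
        model = fit(data, _intercept_spec(offset=1.0), fix_detection=0.5)
        with pytest.warns(UserWarning):
            assert np.isnan(spearman_obs_pred(model, data))


class TestMoranCorrelogram:
    def test_identical_residual_pair_has_unit_moran(self):
        """Two sites with identical nonzero residuals: pair-normalized I = 1."""
        spec = _intercept_spec()
        model = FittedModel(
            params=np.array([np.log(2.0), 0.0, 0.0]), cov=np.zeros((3, 3)),
            loglik=0.0, converged=True, spec=spec, n_sites=2,
        )
        data = RemovalCounts(
            counts=np.array([[3, 0, 0, 0, 0], [3, 0, 0, 0, 0]]),
            covariates=pd.DataFrame(index=[0, 1]),
            jdate=np.zeros(2),
            coords=np.array([[0.0, 0.0], [5000.0, 0.0]]),
        )
        out = residual_moran_correlogram(model, data, max_dist_m=30_000, n_bins=6, nboot=10, seed=0)
        bin_with_pair = out[out["n_pairs"] > 0]
        assert len(bin_with_pair) == 1
        assert bin_with_pair["moran_i"].iloc[0] == pytest.approx(1.0)

    def test_independent_residuals_mostly_inside_envelope(self, default_spec):
        """Across 5 well-specified datasets the observed I stays inside the
        permutation envelope in the vast majority of distance bins."""
        inside = total = 0
        for seed in range(5):
            data = simulate_dataset(seed=100 + seed, n_sites=120)
            model = fit(data, default_spec)
            out = residual_moran_correlogram(
                model, data, max_dist_m=30_000, n_bins=8, nboot=100, seed=seed
            )
            ok = out.dropna(subset=["moran_i"])
            inside += (~ok["outside_envelope"]).sum()
            total += len(ok)
        assert inside / total >= 0.85

    def test_deterministic_given_seed(self, default_spec):
        data = simulate_dataset(seed=30, n_sites=80)
        model = fit(data, default_spec)
        a = residual_moran_correlogram(model, data, nboot=20, seed=9)
        b = residual_moran_correlogram(model, data, nboot=20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_coordinates_raise(self, default_spec):
        data = simulate_dataset(seed=31, n_sites=50)
        data = RemovalCounts(
            counts=data.counts, covariates=data.covariates, jdate=data.jdate, coords=None
        )
        model = fit(data, default_spec)
        with pytest.raises(ConfigurationError):
            residual_moran_correlogram(model, data)
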