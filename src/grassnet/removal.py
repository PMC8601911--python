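"""Removal multinomial-Poisson N-mixture model.

The observed data are removal point counts: at site *i*, the 10-min survey is
split into J = 5 two-minute bins and y_ij individuals are newly detected in
bin j.  The model marginalizes the latent abundance N_i ~ Poisson(λ_i·A)
(log λ_i = x_iᵀβ, A the effective sampled area in km² so λ is a density per
km²) against a geometric removal-detection process with per-bin probability
p_i (logit p_i linear in standardized Julian date):

    π_ij = p_i (1 − p_i)^{j−1},        π_miss,i = (1 − p_i)^J.

Marginalizing N gives the closed-form factorization used here: the total
count T_i = Σ_j y_ij is Poisson with mean λ_i·A·(1 − (1 − p_i)^J) and the
bin split is conditionally multinomial with probabilities π_ij normalized by
1 − (1 − p_i)^J.  Equivalently, the cells y_ij are independent Poissons with
means λ_i·A·π_ij; both forms agree with the truncated latent-N sum.

Fitting is maximum likelihood (BFGS from a zero start, analytic gradient);
the covariance comes from the finite-difference observed information.
Goodness of fit uses a parametric-bootstrap Pearson chi-square; the
overdispersion ratio ĉ (observed over mean bootstrap chi-square, floored at
one) inflates Wald standard errors by √ĉ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, xlogy
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .config import ABUNDANCE_COVARIATES
from .covariates import ScalingParams, abundance_design_matrix
from .errors import ConfigurationError, FittingError, NumericError

#: effective sampled area: circle of 100-m radius, in km²
DEFAULT_OFFSET_AREA_KM2 = np.pi * 0.1**2


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: which covariates enter each component, offset, bins."""

    abundance_covariates: tuple[str, ...] = ABUNDANCE_COVARIATES
    detection_covariates: tuple[str, ...] = ("jdate",)
    offset_area_km2: float = DEFAULT_OFFSET_AREA_KM2
    j_intervals: int = 5

    def __post_init__(self) -> None:
        if self.offset_area_km2 <= 0:
            raise ConfigurationError("offset area must be positive")
        if self.j_intervals < 1:
            raise ConfigurationError("need at least one removal interval")

    @property
    def n_abund(self) -> int:
        return 1 + len(self.abundance_covariates)

    @property
    def n_det(self) -> int:
        return 1 + len(self.detection_covariates)

    @property
    def n_params(self) -> int:
        return self.n_abund + self.n_det

    def param_names(self) -> list[str]:
        return (
            ["abund:intercept"]
            + [f"abund:{n}" for n in self.abundance_covariates]
            + ["det:intercept"]
            + [f"det:{n}" for n in self.detection_covariates]
        )


@dataclass(frozen=True)
class RemovalCounts:
    """Removal counts with the standardized covariates they were observed at."""

    counts: np.ndarray  # (n_sites, J) nonnegative ints
    covariates: pd.DataFrame  # standardized abundance covariates (+ any extras)
    jdate: np.ndarray  # standardized Julian date, length n_sites
    coords: np.ndarray | None = None  # (n_sites, 2) in meters, for correlograms
    site_id: np.ndarray | None = None
    n_true: np.ndarray | None = None  # simulation truth, if known

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ConfigurationError("counts must be (n_sites, J)")
        if (counts < 0).any():
            raise ConfigurationError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(int))
        object.__setattr__(self, "jdate", np.asarray(self.jdate, dtype=float))

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class FittedModel:
    """Maximum-likelihood fit of the removal N-mixture model."""

    params: np.ndarray  # (β_abund..., β_det...)
    cov: np.ndarray  # inverse observed information (unadjusted)
    loglik: float
    converged: bool
    spec: ModelSpec
    scaling: ScalingParams | None = None
    c_hat: float = 1.0  # overdispersion in force (floored at 1 by adjust)
    n_sites: int = 0

    @property
    def beta_abund(self) -> np.ndarray:
        return self.params[: self.spec.n_abund]

    @property
    def beta_det(self) -> np.ndarray:
        return self.params[self.spec.n_abund :]

    @property
    def se_raw(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def se(self) -> np.ndarray:
        """Wald standard errors, inflated by √ĉ."""
        return self.se_raw * np.sqrt(self.c_hat)

    def wald_intervals(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return np.column_stack([self.params - z * self.se, self.params + z * self.se])

    def summary(self) -> pd.DataFrame:
        lo, hi = self.wald_intervals().T
        return pd.DataFrame(
            {
                "parameter": self.spec.param_names(),
                "estimate": self.params,
                "se": self.se,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )


@dataclass(frozen=True)
class GOFResult:
    """Parametric-bootstrap Pearson chi-square goodness of fit."""

    chi2_observed: float
    chi2_bootstrap: np.ndarray
    p_value: float
    c_hat: float
    n_refit_failures: int = 0


def removal_cell_probs(p: float | np.ndarray, j_intervals: int) -> np.ndarray:
    """Interval probabilities (π_1, ..., π_J, π_miss) of the removal process.

    π_j = p(1−p)^{j−1} and π_miss = (1−p)^J; the row sums telescope to one.
    Accepts a scalar or a vector of per-site probabilities; returns an array
    of shape (n, J+1) (or (J+1,) for scalar input).
    """
    scalar = np.isscalar(p)
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise NumericError("detection probability must lie in [0, 1]")
    if j_intervals < 1:
        raise NumericError("j_intervals must be >= 1")
    j = np.arange(j_intervals)
    probs = p_arr[:, None] * (1 - p_arr[:, None]) ** j
    miss = (1 - p_arr) ** j_intervals
    out = np.column_stack([probs, miss])
    return out[0] if scalar else out


def _design_matrices(data: RemovalCounts, spec: ModelSpec):
    x_a = abundance_design_matrix(data.covariates, spec.abundance_covariates)
    x_d = np.column_stack([np.ones(data.n_sites), data.jdate])
    return x_a, x_d


def _nll_core(params, x_a, x_d, totals, late_sum, log_fact, log_a, j_intervals):
    """Negative log-likelihood and its gradient, vectorized over sites.

    ``late_sum`` is Σ_j (j−1)·y_ij and ``log_fact`` is Σ_j log(y_ij!); both
    are the only data summaries the likelihood needs beyond the totals.
    """
    k_a = x_a.shape[1]
    beta_a = params[:k_a]
    beta_d = params[k_a:]
    eta_a = x_a @ beta_a
    eta_d = x_d @ beta_d
    if not (np.all(np.isfinite(eta_a)) and np.all(np.isfinite(eta_d))):
        raise NumericError("non-finite linear predictor")
    mu0 = np.exp(log_a + eta_a)  # λ·A, expected latent abundance
    p = expit(eta_d)
    log_p = -np.logaddexp(0.0, -eta_d)
    log_1mp = -np.logaddexp(0.0, eta_d)
    one_mp_j = np.exp(j_intervals * log_1mp)  # (1−p)^J
    q = -np.expm1(j_intervals * log_1mp)  # 1 − (1−p)^J
    mu = mu0 * q

    nll = float(
        np.sum(mu - totals * (log_a + eta_a) - totals * log_p - late_sum * log_1mp)
        + log_fact
    )
    grad_a = x_a.T @ (mu - totals)
    g_det = mu0 * j_intervals * p * one_mp_j - totals * (1 - p) + late_sum * p
    grad_d = x_d.T @ g_det
    return nll, np.concatenate([grad_a, grad_d])


def _data_summaries(counts: np.ndarray):
    totals = counts.sum(axis=1)
    j = np.arange(counts.shape[1])
    late_sum = counts @ j
    log_fact = float(gammaln(counts + 1).sum())
    return totals, late_sum, log_fact


def marginal_neg_loglik(
    params: np.ndarray, data: RemovalCounts, spec: ModelSpec
) -> float:
    """Closed-form marginal negative log-likelihood of the removal model.

    Equals −Σ_i [log Poisson(T_i; λ_i A q_i) + log Multinomial(y_i; T_i,
    π_ij/q_i)] with q_i = 1 − (1 − p_i)^J, which in turn equals the
    latent-abundance sum Σ_{N ≥ T_i} Poisson(N; λ_i A)·Multinomial(y, N−T
    missed; π) — the brute-force form kept as a test oracle.
    """
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ConfigurationError(
            f"expected {spec.n_params} parameters, got {params.size}"
        )
    x_a, x_d = _design_matrices(data, spec)
    totals, late_sum, log_fact = _data_summaries(data.counts)
    nll, _ = _nll_core(
        params,
        x_a,
        x_d,
        totals,
        late_sum,
        log_fact,
        np.log(spec.offset_area_km2),
        spec.j_intervals,
    )
    return nll


def _hessian_fd(fun_grad, x, step: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient (symmetrized)."""
    k = x.size
    h = np.zeros((k, k))
    for i in range(k):
        d = np.zeros(k)
        d[i] = step * max(1.0, abs(x[i]))
        gp = fun_grad(x + d)[1]
        gm = fun_grad(x - d)[1]
        h[i] = (gp - gm) / (2 * d[i])
    return (h + h.T) / 2


def fit(
    data: RemovalCounts,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    fix_detection: float | None = None,
    maxiter: int = 500,
    gtol: float = 1e-6,
) -> FittedModel:
    """Maximum-likelihood fit by quasi-Newton (BFGS) from a zero start.

    On optimizer failure a single restart from a small deterministic
    perturbation is attempted; a still-unconverged fit is returned flagged,
    not raised.  ``fix_detection`` freezes the per-interval detection
    probability at a constant (no detection parameters are estimated) —
    mainly useful for degenerate checks such as p = 1.
    """
    if data.n_sites < spec.n_params + 1 and fix_detection is None:
        raise FittingError(
            f"need at least {spec.n_params + 1} sites to fit {spec.n_params} parameters"
        )
    x_a, x_d = _design_matrices(data, spec)
    totals, late_sum, log_fact = _data_summaries(data.counts)
    log_a = np.log(spec.offset_area_km2)

    if fix_detection is not None:
        q = 1 - (1 - fix_detection) ** spec.j_intervals
        if q <= 0:
            raise FittingError("fix_detection leaves zero detection probability")

        def fg(beta_a):
            eta = x_a @ beta_a
            mu = np.exp(log_a + eta) * q
            nll = float(np.sum(mu - xlogy(totals, mu)))
            return nll, x_a.T @ (mu - totals)

        x0 = np.zeros(x_a.shape[1]) if start is None else np.asarray(start, float)
    else:

        def fg(params):
            return _nll_core(
                params, x_a, x_d, totals, late_sum, log_fact, log_a, spec.j_intervals
            )

        x0 = np.zeros(spec.n_params) if start is None else np.asarray(start, float)

    res = optimize.minimize(fg, x0, jac=True, method="BFGS",
                            options={"maxiter": maxiter, "gtol": gtol})
    if not res.success:
        res2 = optimize.minimize(
            fg, x0 + 0.1, jac=True, method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        if res2.fun < res.fun or res2.success:
            res = res2

    hess = _hessian_fd(fg, res.x)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise FittingError("singular observed information matrix") from exc
    diag = np.diag(cov)
    if np.any(~np.isfinite(diag)) or np.any(diag < 0):
        raise FittingError("observed information is not positive definite")

    if fix_detection is not None:
        # embed the abundance-only fit in a full-size parameter layout; the
        # fixed p is stored as a (clipped) logit intercept with zero variance
        k_a = x_a.shape[1]
        if fix_detection >= 1.0:
            logit = 35.0
        elif fix_detection <= 0.0:
            logit = -35.0
        else:
            logit = float(np.clip(np.log(fix_detection / (1 - fix_detection)), -35, 35))
        params = np.concatenate([res.x, [logit], np.zeros(spec.n_det - 1)])
        full_cov = np.zeros((spec.n_params, spec.n_params))
        full_cov[:k_a, :k_a] = cov
        cov = full_cov
    else:
        params = res.x

    return FittedModel(
        params=params,
        cov=cov,
        loglik=-float(res.fun),
        converged=bool(res.success),
        spec=spec,
        n_sites=data.n_sites,
    )


def expected_cells(model: FittedModel, data: RemovalCounts) -> np.ndarray:
    """Fitted expected counts per site × interval cell: λ̂_i·A·π̂_ij."""
    x_a, x_d = _design_matrices(data, model.spec)
    mu0 = model.spec.offset_area_km2 * np.exp(x_a @ model.beta_abund)
    p = expit(x_d @ model.beta_det)
    probs = removal_cell_probs(p, model.spec.j_intervals)[:, : model.spec.j_intervals]
    return mu0[:, None] * probs


def _pearson_chi2(observed: np.ndarray, expected: np.ndarray, floor: float = 1e-4) -> float:
    e = np.maximum(expected, floor)
    return float(((observed - e) ** 2 / e).sum())


def simulate_from_model(
    model: FittedModel, data: RemovalCounts, rng: np.random.Generator
) -> RemovalCounts:
    """Parametric simulation of a replicate dataset from the fitted model."""
    x_a, x_d = _design_matrices(data, model.spec)
    mu0 = model.spec.offset_area_km2 * np.exp(x_a @ model.beta_abund)
    p = expit(x_d @ model.beta_det)
    pvals = removal_cell_probs(p, model.spec.j_intervals)
    pvals = pvals / pvals.sum(axis=1, keepdims=True)
    n_latent = rng.poisson(mu0)
    cells = rng.multinomial(n_latent, pvals)
    return replace(data, counts=cells[:, : model.spec.j_intervals], n_true=n_latent)


def gof_parametric_bootstrap(
    model: FittedModel,
    data: RemovalCounts,
    nboot: int = 100,
    seed: int | None = None,
    max_failure_frac: float = 0.2,
) -> GOFResult:
    """Chi-square goodness of fit by parametric bootstrap.

    ``nboot`` replicate datasets are simulated from the fitted model and
    refit; the p-value is the fraction of bootstrap chi-squares at least as
    large as the observed one and ĉ is observed / mean(bootstrap).
    """
    if nboot < 1:
        raise ConfigurationError("nboot must be >= 1")
    if not model.converged:
        raise FittingError("goodness of fit requires a converged model")
    rng = np.random.default_rng(seed)
    obs = _pearson_chi2(data.counts, expected_cells(model, data))
    boots = []
    failures = 0
    for _ in range(nboot):
        sim = simulate_from_model(model, data, rng)
        try:
            refit = fit(sim, model.spec, start=model.params)
        except FittingError:
            failures += 1
            continue
        if not refit.converged:
            failures += 1
            continue
        boots.append(_pearson_chi2(sim.counts, expected_cells(refit, sim)))
    if failures > max_failure_frac * nboot:
        raise FittingError(
            f"{failures}/{nboot} bootstrap refits failed (tolerance {max_failure_frac:.0%})"
        )
    boots = np.asarray(boots)
    return GOFResult(
        chi2_observed=obs,
        chi2_bootstrap=boots,
        p_value=float(np.mean(boots >= obs)),
        c_hat=float(obs / boots.mean()),
        n_refit_failures=failures,
    )


def overdispersion_adjust(model: FittedModel, c_hat: float) -> FittedModel:
    """Apply the overdispersion correction: ĉ′ = max(ĉ, 1), SEs × √ĉ′.

    Point estimates are unchanged; Wald intervals widen through the adjusted
    standard errors.  Estimates of ĉ below one are floored at one.
    """
    if c_hat <= 0:
        raise NumericError("c_hat must be positive")
    return replace(model, c_hat=max(float(c_hat), 1.0))


def predict_expected_density(
    model: FittedModel, covariates_std: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density per km² (point, minus, plus) at standardized covariate rows.

    The error-propagation layers shift *all* abundance coefficients jointly
    by ±1.96 of their (ĉ-adjusted) standard errors, ignoring covariances;
    no ordering between the layers is guaranteed for covariates below their
    mean (negative standardized values flip the shift direction).
    """
    x = abundance_design_matrix(covariates_std, model.spec.abundance_covariates)
    beta = model.beta_abund
    se = model.se[: model.spec.n_abund]

    def link(eta):
        # clip below the float64 overflow point: extreme extrapolation far
        # outside the fitting range must stay finite rather than become inf
        return np.exp(np.clip(eta, -700.0, 700.0))

    return link(x @ beta), link(x @ (beta - 1.96 * se)), link(x @ (beta + 1.96 * se))


def covariate_effect_size(model: FittedModel, covariate_name: str) -> dict:
    """Change in predicted density for a +1 SD move of one covariate.

    All other covariates are held at their means (standardized zero), so the
    ratio is exactly exp(b) for fitted coefficient b; the interval uses the
    ĉ-adjusted standard error.
    """
    names = model.spec.abundance_covariates
    if covariate_name not in names:
        raise ConfigurationError(f"unknown covariate {covariate_name!r}")
    idx = 1 + names.index(covariate_name)
    b = model.beta_abund[idx]
    se_b = model.se[idx]
    base = float(np.exp(model.beta_abund[0]))
    shifted = float(np.exp(model.beta_abund[0] + b))
    return {
        "covariate": covariate_name,
        "density_at_mean": base,
        "density_plus_1sd": shifted,
        "absolute_change": shifted - base,
        "ratio": float(np.exp(b)),
        "ratio_ci": (float(np.exp(b - 1.96 * se_b)), float(np.exp(b + 1.96 * se_b))),
    }


def expected_totals(model: FittedModel, data: RemovalCounts) -> np.ndarray:
    """Predicted expected total count per site: λ̂·A·(1 − (1 − p̂)^J)."""
    x_a, x_d = _design_matrices(data, model.spec)
    mu0 = model.spec.offset_area_km2 * np.exp(x_a @ model.beta_abund)
    p = expit(x_d @ model.beta_det)
    return mu0 * (1 - (1 - p) ** model.spec.j_intervals)


def _split(n: int, holdout_frac: float, rng: np.random.Generator):
    if not 0 < holdout_frac < 1:
        raise ConfigurationError("holdout_frac must lie in (0, 1)")
    idx = rng.permutation(n)
    n_test = max(int(round(holdout_frac * n)), 1)
    return idx[n_test:], idx[:n_test]


def _subset(data: RemovalCounts, idx: np.ndarray) -> RemovalCounts:
    return RemovalCounts(
        counts=data.counts[idx],
        covariates=data.covariates.iloc[idx].reset_index(drop=True),
        jdate=data.jdate[idx],
        coords=None if data.coords is None else data.coords[idx],
        site_id=None if data.site_id is None else data.site_id[idx],
    )


def crossval_holdout(
    data: RemovalCounts,
    spec: ModelSpec,
    holdout_frac: float = 0.3,
    seed: int | None = None,
) -> dict:
    """Single 70/30 holdout: fit on the training split, score the holdout.

    Reports RMSE and MAE between observed and predicted expected totals on
    the held-out sites, plus the training-fit convergence flag.
    """
    rng = np.random.default_rng(seed)
    train, test = _split(data.n_sites, holdout_frac, rng)
    model = fit(_subset(data, train), spec)
    test_data = _subset(data, test)
    pred = expected_totals(model, test_data)
    err = test_data.totals - pred
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "n_test": len(test),
        "train_converged": model.converged,
    }


def auc_holdout(
    data: RemovalCounts,
    spec: ModelSpec,
    holdout_frac: float = 0.3,
    reps: int = 10,
    seed: int | None = None,
    acceptable_threshold: float = 0.6,
) -> dict:
    """Mean holdout AUC over repeated 70/30 splits.

    For each repetition the model is fit on 70% of sites and the holdout
    detection indicator (total count > 0) is ranked by the predicted
    detection probability 1 − exp(−λ̂A(1 − (1 − p̂)^J)).  Splits whose
    holdout contains a single class are skipped with a warning.  Mean AUC
    above ``acceptable_threshold`` counts as acceptable predictive accuracy.
    """
    rng = np.random.default_rng(seed)
    aucs = []
    for r in range(reps):
        train, test = _split(data.n_sites, holdout_frac, rng)
        test_data = _subset(data, test)
        detected = (test_data.totals > 0).astype(int)
        if detected.min() == detected.max():
            warnings.warn(f"AUC rep {r}: single-class holdout, skipped", stacklevel=2)
            continue
        model = fit(_subset(data, train), spec)
        p_detect = 1 - np.exp(-expected_totals(model, test_data))
        aucs.append(float(roc_auc_score(detected, p_detect)))
    if not aucs:
        raise FittingError("every AUC repetition had a single-class holdout")
    mean_auc = float(np.mean(aucs))
    return {
        "mean_auc": mean_auc,
        "per_rep": aucs,
        "acceptable": mean_auc > acceptable_threshold,
    }


def spearman_obs_pred(model: FittedModel, data: RemovalCounts) -> float:
    """Spearman rank correlation between observed and predicted totals."""
    pred = expected_totals(model, data)
    if np.ptp(pred) == 0 or np.ptp(data.totals) == 0:
        warnings.warn("constant observed or predicted totals; rho undefined", stacklevel=2)
        return float("nan")
    rho, _ = spearmanr(data.totals, pred)
    return float(rho)


def pearson_residuals(model: FittedModel, data: RemovalCounts) -> np.ndarray:
    """(T − E[T]) / √Var[T] with Poisson variance for the totals."""
    mu = expected_totals(model, data)
    return (data.totals - mu) / np.sqrt(np.maximum(mu, 1e-12))


def residual_moran_correlogram(
    model: FittedModel,
    data: RemovalCounts,
    max_dist_m: float = 30_000.0,
    n_bins: int = 10,
    nboot: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binned Moran's I of Pearson residuals with a permutation envelope.

    Pair products of (uncentered) residuals are averaged per distance bin and
    normalized by the mean squared residual; ``nboot`` site-label
    permutations give a 95% null envelope per bin.  Bins whose envelope
    covers the observed I (equivalently, I indistinguishable from zero)
    indicate no residual spatial autocorrelation at that distance.  Bins with
    fewer than one pair are reported empty (NaN).
    """
    if data.coords is None:
        raise ConfigurationError("site coordinates are required for a correlogram")
    rng = np.random.default_rng(seed)
    z = pearson_residuals(model, data)
    n = len(z)
    xy = np.asarray(data.coords, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    dist = d[iu]
    keep = dist <= max_dist_m
    dist = dist[keep]
    ii, jj = iu[0][keep], iu[1][keep]
    edges = np.linspace(0, max_dist_m, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)

    def binned_i(vals: np.ndarray) -> np.ndarray:
        denom = float(np.mean(vals**2))
        prod = vals[ii] * vals[jj]
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = which == b
            if m.sum() >= 1 and denom > 0:
                out[b] = float(prod[m].mean() / denom)
        return out

    observed = binned_i(z)
    null = np.array([binned_i(z[rng.permutation(n)]) for _ in range(nboot)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(null, 2.5, axis=0)
        hi = np.nanpercentile(null, 97.5, axis=0)
    n_pairs = np.array([(which == b).sum() for b in range(n_bins)])
    return pd.DataFrame(
        {
            "bin_lo_m": edges[:-1],
            "bin_hi_m": edges[1:],
            "n_pairs": n_pairs,
            "moran_i": observed,
            "env_lo": lo,
            "env_hi": hi,
            "outside_envelope": (observed < lo) | (observed > hi),
        }
    )
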