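"""Combination learners: BP feed-forward network and (mixed) logistic regression.

Two learners map a shock's feature vector (AMSA alone or combined with PSI
and/or dAMSA) to a success probability:

* a small back-propagation network, inputs -> 3 logistic-sigmoid units ->
  2 linear units -> 1 logistic-sigmoid output, trained by minimising
  cross-entropy plus an L2 weight penalty whose strength is re-estimated
  with the evidence approximation (Bayesian-regularisation style
  ``lambda <- gamma / (2 sum w^2)`` with ``gamma`` the effective number of
  parameters);
* logistic regression, either pooled or with a patient-level random
  intercept whose likelihood is integrated by adaptive Gauss-Hermite
  quadrature (the repeated shocks of one patient are dependent events).

Scores for new patients use the marginal (random intercept = 0)
prediction, since an unseen patient's intercept is unobservable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.special import expit, log_expit
from scipy.stats import norm

from .errors import DegenerateTrainingError, InvalidArgumentError, SchemaError
from .features import FEATURE_SETS

__all__ = [
    "BpNetworkModel", "LogisticModel", "RegressionResult",
    "train_bp_network", "fit_logistic", "fit_all_combinations", "predict_score",
]

_HIDDEN1 = 3  # logistic-sigmoid units
_HIDDEN2 = 2  # linear units

_SCORE_EPS = 1e-12


@dataclass
class RegressionResult:
    """Odds ratio with Wald 95% CI and p-value for one covariate."""

    covariate: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if np.isfinite(self.odds_ratio) and not (
            self.ci_low <= self.odds_ratio <= self.ci_high
        ):
            raise InvalidArgumentError("CI must bracket the odds ratio")


@dataclass
class LogisticModel:
    """Pooled or random-intercept logistic regression fit."""

    covariates: list[str]
    coef: np.ndarray            # log-odds per unit of each covariate
    intercept: float
    random_intercept_sd: float  # 0 => pooled model
    cov_params: np.ndarray      # covariance of (intercept, coef...) estimates
    log_likelihood: float
    converged: bool
    n_obs: int
    n_groups: int
    results: list[RegressionResult] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return len(self.covariates)


@dataclass
class BpNetworkModel:
    """Trained feed-forward network (inputs -> 3 sigmoid -> 2 linear -> sigmoid)."""

    covariates: list[str]
    theta: np.ndarray           # packed weights and biases
    input_mean: np.ndarray      # training-column standardisation
    input_scale: np.ndarray
    regularization_weight: float
    seed: int
    training_trace: list[np.ndarray]  # objective per iteration, one array per stage
    converged: bool

    @property
    def n_inputs(self) -> int:
        return len(self.covariates)

    @property
    def layer_sizes(self) -> tuple[int, int, int, int]:
        return (self.n_inputs, _HIDDEN1, _HIDDEN2, 1)


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _n_params(d: int) -> int:
    return (d + 1) * _HIDDEN1 + (_HIDDEN1 + 1) * _HIDDEN2 + (_HIDDEN2 + 1)


def _unpack(theta: np.ndarray, d: int):
    i = 0
    w1 = theta[i:i + d * _HIDDEN1].reshape(_HIDDEN1, d); i += d * _HIDDEN1
    b1 = theta[i:i + _HIDDEN1]; i += _HIDDEN1
    w2 = theta[i:i + _HIDDEN1 * _HIDDEN2].reshape(_HIDDEN2, _HIDDEN1)
    i += _HIDDEN1 * _HIDDEN2
    b2 = theta[i:i + _HIDDEN2]; i += _HIDDEN2
    w3 = theta[i:i + _HIDDEN2]; i += _HIDDEN2
    b3 = theta[i]
    return w1, b1, w2, b2, w3, b3


def _forward(theta: np.ndarray, x: np.ndarray):
    w1, b1, w2, b2, w3, b3 = _unpack(theta, x.shape[1])
    a1 = expit(x @ w1.T + b1)          # (n, 3) sigmoid
    a2 = a1 @ w2.T + b2                # (n, 2) linear
    z3 = a2 @ w3 + b3                  # (n,)
    return a1, a2, z3, expit(z3)


def _objective(theta: np.ndarray, x: np.ndarray, y: np.ndarray, lam: float):
    """Summed cross-entropy + lam * sum(theta^2), with analytic gradient."""
    a1, a2, z3, p = _forward(theta, x)
    # stable cross-entropy via log-sigmoid
    ce = -np.sum(y * log_expit(z3) + (1.0 - y) * log_expit(-z3))
    loss = ce + lam * np.dot(theta, theta)

    w1, b1, w2, b2, w3, b3 = _unpack(theta, x.shape[1])
    d3 = p - y                          # (n,)
    g_w3 = d3 @ a2
    g_b3 = d3.sum()
    d2 = np.outer(d3, w3)               # (n, 2)
    g_w2 = d2.T @ a1
    g_b2 = d2.sum(axis=0)
    d1 = (d2 @ w2) * a1 * (1.0 - a1)    # (n, 3)
    g_w1 = d1.T @ x
    g_b1 = d1.sum(axis=0)
    grad = np.concatenate(
        [g_w1.ravel(), g_b1, g_w2.ravel(), g_b2, g_w3, [g_b3]]
    ) + 2.0 * lam * theta
    return loss, grad


def _data_hessian(theta: np.ndarray, x: np.ndarray, y: np.ndarray,
                  eps: float = 1e-5) -> np.ndarray:
    """Finite-difference Hessian of the (unpenalised) data term."""
    p = theta.size
    hess = np.empty((p, p))
    for j in range(p):
        tp = theta.copy(); tp[j] += eps
        tm = theta.copy(); tm[j] -= eps
        gp = _objective(tp, x, y, 0.0)[1]
        gm = _objective(tm, x, y, 0.0)[1]
        hess[j] = (gp - gm) / (2.0 * eps)
    return 0.5 * (hess + hess.T)


def train_bp_network(
    frame: pd.DataFrame,
    covariates,
    *,
    lam_policy: str = "evidence",
    lam0: float = 0.01,
    seed: int = 0,
    max_iter: int = 400,
    n_evidence_updates: int = 3,
) -> BpNetworkModel:
    """Train the combination network on a feature table.

    ``frame`` must contain the covariate columns and a binary ``outcome``
    column.  Inputs are standardised by training-column z-scores
    (zero-variance columns get unit scale).  ``lam_policy`` is ``"evidence"``
    (re-estimate the L2 weight ``lambda = gamma / (2 sum w^2)`` between
    optimisation stages, with ``gamma = sum h_i / (h_i + 2 lambda)`` over
    the data-term Hessian eigenvalues) or ``"fixed"`` (keep ``lam0``).
    Deterministic given ``seed``.
    """
    covariates = list(covariates)
    x_raw = frame[list(covariates)].to_numpy(dtype=float)
    y = frame["outcome"].to_numpy(dtype=float)
    if x_raw.shape[0] < 4 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise DegenerateTrainingError("need at least 2 rows per outcome class")
    if not np.all(np.isfinite(x_raw)):
        raise InvalidArgumentError("features must be finite")
    if lam_policy not in ("evidence", "fixed"):
        raise InvalidArgumentError(f"unknown lam_policy {lam_policy!r}")

    mu = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (x_raw - mu) / sd

    rng = np.random.default_rng(seed)
    theta = rng.normal(0.0, 0.5, size=_n_params(x.shape[1]))
    lam = float(lam0)
    trace: list[np.ndarray] = []
    converged = True
    n_stages = n_evidence_updates + 1 if lam_policy == "evidence" else 1
    for stage in range(n_stages):
        stage_vals: list[float] = []

        def _cb(tk, _x=x, _y=y, _lam=lam, _vals=stage_vals):
            _vals.append(_objective(tk, _x, _y, _lam)[0])

        res = optimize.minimize(
            _objective, theta, args=(x, y, lam), jac=True,
            method="L-BFGS-B", callback=_cb,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
        )
        theta = res.x
        trace.append(np.asarray(stage_vals))
        converged = bool(res.success) or res.status == 1  # 1 = maxiter reached
        if not res.success and res.status != 1:
            warnings.warn(f"network optimisation flagged: {res.message}",
                          stacklevel=2)
            converged = False
        if lam_policy == "evidence" and stage < n_stages - 1:
            h = np.linalg.eigvalsh(_data_hessian(theta, x, y))
            h = np.clip(h, 0.0, None)
            gamma = float(np.sum(h / (h + 2.0 * lam)))
            ssw = float(np.dot(theta, theta))
            lam = float(np.clip(gamma / max(2.0 * ssw, 1e-12), 1e-6, 1e3))
    return BpNetworkModel(
        covariates=covariates, theta=theta, input_mean=mu, input_scale=sd,
        regularization_weight=lam, seed=seed, training_trace=trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# logistic regression (pooled and random-intercept)
# ---------------------------------------------------------------------------

def _group_index(groups: np.ndarray):
    """Sort observations by group; return order, group start offsets."""
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    return order, starts


def _mixed_loglik(params: np.ndarray, x: np.ndarray, y: np.ndarray,
                  starts: np.ndarray, nodes: np.ndarray, weights: np.ndarray,
                  newton_iter: int = 30) -> float:
    """Random-intercept logistic log-likelihood via adaptive Gauss-Hermite.

    ``params`` = (intercept, beta..., log sigma_b).  Observations must be
    sorted by group with group boundaries in ``starts``.  Each evaluation
    re-centres the quadrature at the per-group posterior mode (Newton) and
    rescales by the posterior curvature.
    """
    intercept, beta, log_sigma = params[0], params[1:-1], params[-1]
    sigma2 = np.exp(2.0 * log_sigma)
    eta = intercept + x @ beta
    n_groups = starts.size
    counts = np.diff(np.r_[starts, y.size])

    b = np.zeros(n_groups)
    for _ in range(newton_iter):
        p = expit(eta + np.repeat(b, counts))
        grad = np.add.reduceat(y - p, starts) - b / sigma2
        hess = -np.add.reduceat(p * (1.0 - p), starts) - 1.0 / sigma2
        step = np.clip(-grad / hess, -4.0, 4.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    tau = 1.0 / np.sqrt(np.add.reduceat(expit(eta + np.repeat(b, counts))
                                        * expit(-(eta + np.repeat(b, counts))),
                                        starts) + 1.0 / sigma2)

    # h(b) = sum_j log lik_j(b) + log N(b; 0, sigma2); integrate exp(h)
    log_vals = np.empty((nodes.size, n_groups))
    for k, (z, w) in enumerate(zip(nodes, weights)):
        bk = b + tau * z
        eta_k = eta + np.repeat(bk, counts)
        ll = np.add.reduceat(y * log_expit(eta_k) + (1 - y) * log_expit(-eta_k),
                             starts)
        log_prior = -0.5 * bk**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        # probabilists' Hermite weights absorb exp(-z^2/2); add it back
        log_vals[k] = np.log(w) + 0.5 * z**2 + ll + log_prior
    m = log_vals.max(axis=0)
    log_li = m + np.log(np.sum(np.exp(log_vals - m), axis=0)) + np.log(tau)
    return float(np.sum(log_li))


def _fit_mixed_logit(x: np.ndarray, y: np.ndarray, groups: np.ndarray,
                     n_quad: int = 15):
    """ML fit of the random-intercept logistic model.

    Returns (intercept, beta, sigma_b, cov of (intercept, beta), loglik,
    converged).  The covariance is the inverse observed-information block
    of the fixed effects from a finite-difference Hessian.
    """
    order, starts = _group_index(groups)
    xs, ys = x[order], y[order]
    nodes, weights = hermegauss(n_quad)

    start_model = sm.Logit(ys, sm.add_constant(xs, has_constant="add"))
    try:
        start_fit = start_model.fit(disp=0)
        x0 = np.r_[start_fit.params, 0.0]
    except Exception:
        x0 = np.zeros(x.shape[1] + 2)

    def negll(p):
        return -_mixed_loglik(p, xs, ys, starts, nodes, weights)

    bounds = [(None, None)] * (x.shape[1] + 1) + [(-7.0, 3.0)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 300, "ftol": 1e-11})
    params = res.x
    # observed information via central differences on the gradient
    p_dim = params.size
    eps = 1e-4 * np.maximum(1.0, np.abs(params))
    hess = np.empty((p_dim, p_dim))
    for j in range(p_dim):
        pp = params.copy(); pp[j] += eps[j]
        pm = params.copy(); pm[j] -= eps[j]
        gp = optimize.approx_fprime(pp, negll, 1e-6)
        gm = optimize.approx_fprime(pm, negll, 1e-6)
        hess[j] = (gp - gm) / (2.0 * eps[j])
    hess = 0.5 * (hess + hess.T)
    try:
        cov_all = np.linalg.pinv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.full((p_dim, p_dim), np.nan)
    cov_fixed = cov_all[: p_dim - 1, : p_dim - 1]
    sigma_b = float(np.exp(params[-1]))
    converged = bool(res.success) and np.all(np.isfinite(params))
    if np.max(np.abs(params[:-1])) > 50:
        converged = False  # likely separation
    return params[0], params[1:-1], sigma_b, cov_fixed, -res.fun, converged


def fit_logistic(
    frame: pd.DataFrame,
    covariates,
    *,
    random_intercept: bool = True,
    groups: str = "patient_id",
    n_quad: int = 15,
) -> tuple[LogisticModel, list[RegressionResult]]:
    """Fit a (random-intercept) logistic regression to a feature table.

    Zero-variance covariates are dropped before fitting (they carry no
    information and would make the design singular); the returned model
    lists only the fitted covariates.  Odds ratios use Wald 95% CIs on the
    log scale.
    """
    covariates = [c for c in covariates]
    kept = [c for c in covariates
            if np.std(frame[c].to_numpy(dtype=float)) > 0]
    if not kept:
        raise DegenerateTrainingError("all covariates are constant")
    x = frame[kept].to_numpy(dtype=float)
    y = frame["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateTrainingError("both outcome classes must be present")

    if random_intercept:
        g = frame[groups].to_numpy()
        if np.unique(g).size < 2:
            raise DegenerateTrainingError(
                "random-intercept model needs at least 2 patients"
            )
        intercept, beta, sigma_b, cov_fixed, llf, converged = _fit_mixed_logit(
            x, y, g, n_quad=n_quad
        )
        n_groups = int(np.unique(g).size)
    else:
        model = sm.Logit(y, sm.add_constant(x, has_constant="add"))
        try:
            fit = model.fit(disp=0)
        except Exception as exc:  # includes perfect separation
            raise DegenerateTrainingError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(fit.params)) or np.max(np.abs(fit.params)) > 50:
            raise DegenerateTrainingError("non-finite estimates (separation?)")
        intercept, beta = float(fit.params[0]), np.asarray(fit.params[1:])
        sigma_b = 0.0
        cov_fixed = np.asarray(fit.cov_params())
        llf = float(fit.llf)
        converged = bool(fit.mle_retvals.get("converged", True))
        n_groups = int(frame[groups].nunique()) if groups in frame else len(frame)

    results = []
    for j, name in enumerate(kept):
        se = float(np.sqrt(max(cov_fixed[j + 1, j + 1], 0.0)))
        bj = float(beta[j])
        z = bj / se if se > 0 else np.inf * np.sign(bj)
        results.append(RegressionResult(
            covariate=name,
            odds_ratio=float(np.exp(bj)),
            ci_low=float(np.exp(bj - 1.959963984540054 * se)),
            ci_high=float(np.exp(bj + 1.959963984540054 * se)),
            p_value=float(2.0 * norm.sf(abs(z))),
        ))
    model_out = LogisticModel(
        covariates=kept, coef=np.asarray(beta, dtype=float),
        intercept=float(intercept), random_intercept_sd=float(sigma_b),
        cov_params=cov_fixed, log_likelihood=float(llf),
        converged=converged, n_obs=len(frame), n_groups=n_groups,
        results=results,
    )
    return model_out, results


# ---------------------------------------------------------------------------
# prediction and the four feature combinations
# ---------------------------------------------------------------------------

def predict_score(model, frame: pd.DataFrame) -> np.ndarray:
    """Per-row success probability in (0, 1) from either learner.

    For the random-intercept logistic model the prediction is marginal
    (random intercept set to 0), appropriate for patients unseen in
    training.
    """
    missing = [c for c in model.covariates if c not in frame.columns]
    if missing:
        raise SchemaError(f"rows are missing covariates {missing}")
    x = frame[list(model.covariates)].to_numpy(dtype=float)
    if isinstance(model, BpNetworkModel):
        z = (x - model.input_mean) / model.input_scale
        scores = _forward(model.theta, z)[3]
    elif isinstance(model, LogisticModel):
        scores = expit(model.intercept + x @ model.coef)
    else:
        raise InvalidArgumentError(f"unknown model type {type(model).__name__}")
    return np.clip(scores, _SCORE_EPS, 1.0 - _SCORE_EPS)


def fit_all_combinations(
    frame: pd.DataFrame,
    method: str = "network",
    seed: int = 0,
    *,
    random_intercept: bool = True,
    lam_policy: str = "evidence",
) -> dict[str, object]:
    """Fit AMSA, C1, C2 and C3 models on the same training rows.

    Network seeds are fanned out from ``seed`` per feature set; the
    logistic fits have no random initialisation and ignore the seed.
    """
    if method not in ("network", "logistic"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(FEATURE_SETS))
    models: dict[str, object] = {}
    for (name, cols), s in zip(FEATURE_SETS.items(), sub_seeds):
        if method == "network":
            models[name] = train_bp_network(
                frame, cols, seed=int(s % (2**31)), lam_policy=lam_policy
            )
        else:
            models[name], _ = fit_logistic(
                frame, cols, random_intercept=random_intercept
            )
    return models
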