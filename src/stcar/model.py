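"""The probability model as pure functions of a parameter state.

Counts follow ``O_it ~ Poisson(E_it * RR_it)`` with expected counts from
internal standardization, ``E_it = rho_it * Rbar`` where ``Rbar`` is the
pooled incidence rate over all areas and years.  The log relative risk
decomposes into an intercept, spatially structured (ICAR) and unstructured
(iid Normal) area effects, two covariate terms, a mean linear time trend and
an area-specific differential trend:

    log RR_it = alpha + U_i + V_i + b_thi * X~_it + b_ebf * X~_i
                + (gamma + delta_i) * t~

Covariates are mean-centered (X~) and model time is centered at its midpoint
(t~ = t - (T+1)/2); centering changes only the interpretation of the
intercept, not the slopes or the fitted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .panel import AdjacencyGraph, ArealPanel


@dataclass
class ExpectedCounts:
    """Expected counts ``E_it`` and the pooled rate ``Rbar`` behind them."""

    e: np.ndarray
    overall_rate: float


def compute_expected_counts(panel: ArealPanel) -> ExpectedCounts:
    """Internal standardization: Rbar = sum(O)/sum(rho), E_it = rho_it * Rbar.

    The identity sum(E) == sum(O) holds by construction.
    """
    total = panel.counts.sum()
    if total <= 0:
        raise ValueError("all counts are zero: pooled rate is 0 and the model is undefined")
    rbar = float(total / panel.populations.sum())
    return ExpectedCounts(e=panel.populations * rbar, overall_rate=rbar)


@dataclass
class PriorSpec:
    """Prior settings for the hierarchical model.

    ``coef_precision`` is the precision (1/variance, WinBUGS convention) of
    the zero-mean Normal prior shared by the slope and trend coefficients;
    the default 1e-4 corresponds to variance 10,000 (essentially flat).  The
    intercept prior is improper flat.  Each random-effect precision
    ``1/sigma^2`` has a Gamma(hyper_shape, hyper_rate) prior, unless
    ``variance_prior`` is ``"uniform_sigma"`` in which case the standard
    deviation itself is Uniform(0, sigma_upper).
    """

    coef_precision: float = 1e-4
    hyper_shape: float = 0.5
    hyper_rate: float = 5e-4
    variance_prior: str = "gamma"
    sigma_upper: float = 1000.0

    def __post_init__(self) -> None:
        if self.coef_precision <= 0:
            raise ValueError("coef_precision must be > 0")
        if self.hyper_shape <= 0 or self.hyper_rate <= 0:
            raise ValueError("Gamma hyperparameters must be > 0")
        if self.variance_prior not in ("gamma", "uniform_sigma"):
            raise ValueError("variance_prior must be 'gamma' or 'uniform_sigma'")
        if self.sigma_upper <= 0:
            raise ValueError("sigma_upper must be > 0")


@dataclass
class ParameterDraw:
    """One state of the model: fixed effects, random-effect fields, variances."""

    alpha: float
    beta_thi: float
    beta_ebf: float
    gamma: float
    u: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    sigma2_u: float
    sigma2_v: float
    sigma2_delta: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if min(self.sigma2_u, self.sigma2_v, self.sigma2_delta) <= 0:
            raise ValueError("variances must be > 0")

    @classmethod
    def zeros(cls, n: int, sigma2: float = 1.0) -> "ParameterDraw":
        z = np.zeros(n)
        return cls(alpha=0.0, beta_thi=0.0, beta_ebf=0.0, gamma=0.0,
                   u=z.copy(), v=z.copy(), delta=z.copy(),
                   sigma2_u=sigma2, sigma2_v=sigma2, sigma2_delta=sigma2)


def centered_covariates(panel: ArealPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered covariates and centered time: (X~_thi (N,T), X~_ebf (N,), t~ (T,))."""
    return (panel.thi - panel.thi.mean(),
            panel.ebf - panel.ebf.mean(),
            panel.centered_time())


def linear_predictor(draw: ParameterDraw, panel: ArealPanel) -> np.ndarray:
    """log RR_it surface, shape (N, T)."""
    if draw.u.shape != (panel.N,) or draw.v.shape != (panel.N,) or draw.delta.shape != (panel.N,):
        raise ValueError("random-effect dimensions do not match the panel")
    x_thi, x_ebf, t_c = centered_covariates(panel)
    return (draw.alpha
            + draw.u[:, None] + draw.v[:, None]
            + draw.beta_thi * x_thi
            + draw.beta_ebf * x_ebf[:, None]
            + (draw.gamma + draw.delta[:, None]) * t_c[None, :])


def relative_risk(draw: ParameterDraw, panel: ArealPanel) -> np.ndarray:
    """RR_it = exp(log-linear predictor); strictly positive, shape (N, T)."""
    return np.exp(linear_predictor(draw, panel))


def poisson_loglik(counts: np.ndarray, mu: np.ndarray) -> float:
    """Full Poisson log-likelihood sum(O log mu - mu - log O!)."""
    counts = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if counts.shape != mu.shape:
        raise ValueError("shape mismatch between counts and means")
    if np.any(mu <= 0):
        raise ValueError("Poisson means must be positive")
    return float(np.sum(counts * np.log(mu) - mu - gammaln(counts + 1.0)))


def panel_loglik(panel: ArealPanel, e: ExpectedCounts, rr: np.ndarray) -> float:
    """Log-likelihood of the panel at means mu_it = E_it * RR_it."""
    return poisson_loglik(panel.counts, e.e * rr)


def icar_quadratic(field_values: np.ndarray, graph: AdjacencyGraph) -> float:
    """Pairwise-difference energy sum over edges of (f_i - f_j)^2, each edge once."""
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    d = field_values[i] - field_values[j]
    return float(d @ d)


def log_prior(draw: ParameterDraw, graph: AdjacencyGraph, spec: PriorSpec) -> float:
    """Joint log prior density (up to additive constants).

    ICAR terms for the spatial and differential-trend fields use the rank
    ``N - c`` (c = connected components) as the degrees of freedom of the
    improper Gaussian; the intercept contributes 0 (flat).
    """
    n = graph.n_nodes
    nstar = n - graph.n_components
    lp = 0.0
    # ICAR fields
    for f, s2 in ((draw.u, draw.sigma2_u), (draw.delta, draw.sigma2_delta)):
        q = icar_quadratic(f, graph)
        lp += -0.5 * q / s2 + 0.5 * nstar * np.log(1.0 / s2)
    # iid Normal heterogeneity
    lp += -0.5 * np.sum(draw.v**2) / draw.sigma2_v - 0.5 * n * np.log(draw.sigma2_v)
    # coefficients: Normal(0, 1/coef_precision)
    tau = spec.coef_precision
    for b in (draw.beta_thi, draw.beta_ebf, draw.gamma):
        lp += -0.5 * tau * b * b
    # variance hyperpriors
    for s2 in (draw.sigma2_u, draw.sigma2_v, draw.sigma2_delta):
        lp += _log_variance_prior(s2, spec)
    return float(lp)


def _log_variance_prior(s2: float, spec: PriorSpec) -> float:
    """Log prior density of one random-effect variance, in the variance parameter."""
    if spec.variance_prior == "gamma":
        # precision ~ Gamma(a, b); density in s2 via change of variables
        a, b = spec.hyper_shape, spec.hyper_rate
        prec = 1.0 / s2
        return float((a - 1) * np.log(prec) - b * prec - 2.0 * np.log(s2))
    # sigma ~ Uniform(0, upper): density in s2 proportional to s2^{-1/2}
    if np.sqrt(s2) >= spec.sigma_upper:
        return -np.inf
    return float(-0.5 * np.log(s2))
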