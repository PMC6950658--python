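"""Posterior summaries, convergence and fit diagnostics, and derived reports.

Everything downstream of the sampler lives here: per-parameter summary rows
(mean, SD, equal-tailed 95% credible interval, batch-means Monte Carlo
error), the Brooks-Gelman-Rubin potential scale reduction factor, DIC,
exceedance and sign probabilities, multiplicative covariate effect factors,
per-area differential trends, and the prior-sensitivity comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import MCMCConfig, PosteriorSamples, run_chains
from .model import PriorSpec, compute_expected_counts, panel_loglik, relative_risk
from .panel import AdjacencyGraph, ArealPanel

MC_ERROR_RULE = 0.05  # MC error should be below 5% of the posterior SD
SIGN_RELEVANCE = 0.90  # sign probability above 90% flags a relevant coefficient


@dataclass
class SummaryRow:
    parameter: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    mc_error: float

    @property
    def mc_error_ok(self) -> bool:
        """Rule of thumb: MC error below 5% of the posterior SD (trivially met
        for a degenerate, zero-variance chain)."""
        return self.mc_error <= MC_ERROR_RULE * self.sd or self.sd == 0.0


def mc_error_batch_means(draws: np.ndarray) -> float:
    """Monte Carlo standard error of the mean by batch means.

    Uses ceil(sqrt(n)) batches of equal size (a trailing remainder is
    dropped), which is consistent for geometrically ergodic chains.
    """
    x = np.asarray(draws, dtype=float).reshape(-1)
    n = x.size
    if n < 2:
        return 0.0
    nb = int(np.ceil(np.sqrt(n)))
    m = n // nb
    if m < 1:
        nb, m = n, 1
    means = x[: nb * m].reshape(nb, m).mean(axis=1)
    if nb < 2:
        return 0.0
    return float(np.std(means, ddof=1) / np.sqrt(nb))


def summarize(samples: PosteriorSamples, param: str) -> SummaryRow:
    """Pooled-chain posterior summary of one parameter."""
    x = samples.get(param)
    if x.size < 100:
        raise ValueError(f"need at least 100 retained draws, have {x.size}")
    lo, hi = np.percentile(x, [2.5, 97.5])
    return SummaryRow(parameter=param, mean=float(x.mean()), sd=float(x.std(ddof=1)),
                      ci_low=float(lo), ci_high=float(hi),
                      mc_error=mc_error_batch_means(x))


def summary_table(samples: PosteriorSamples, include_fields: bool = True) -> pd.DataFrame:
    """Summary rows for every model parameter (optionally skipping the fields)."""
    names = samples.param_names()
    if not include_fields:
        names = [n for n in names if "[" not in n]
    rows = [summarize(samples, n) for n in names]
    return pd.DataFrame(
        {"parameter": [r.parameter for r in rows], "mean": [r.mean for r in rows],
         "sd": [r.sd for r in rows], "ci2.5": [r.ci_low for r in rows],
         "ci97.5": [r.ci_high for r in rows], "mc_error": [r.mc_error for r in rows]})


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains.

    sqrt(Vhat / W) with W the mean within-chain variance and
    Vhat = (n-1)/n W + B/n.  A degenerate set of chains (all constant)
    returns exactly 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length (use split chains for one chain)")
    m, n = x.shape
    if n < 10:
        raise ValueError("chains too short for a stable diagnostic")
    w = x.var(axis=1, ddof=1).mean()
    b = n * x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    vhat = (n - 1) / n * w + b / n
    return float(np.sqrt(vhat / w))


def rhat_table(samples: PosteriorSamples, include_fields: bool = True) -> dict[str, float]:
    names = samples.param_names()
    if not include_fields:
        names = [n for n in names if "[" not in n]
    return {n: gelman_rubin(samples.chains(n)) for n in names}


@dataclass
class FitDiagnostics:
    """DIC decomposition plus per-parameter convergence diagnostics."""

    dbar: float
    d_hat: float
    p_d: float
    dic: float
    rhat: dict[str, float]


def dic(samples: PosteriorSamples, panel: ArealPanel,
        include_field_rhat: bool = False) -> FitDiagnostics:
    """Deviance information criterion: DIC = Dbar + pD, pD = Dbar - D(theta_bar).

    ``Dbar`` averages the full Poisson deviance -2 log L over retained draws;
    ``D(theta_bar)`` plugs in the posterior means of every parameter on the
    natural scale (intercept, slopes, trend, and each random-effect
    component), not the mean of the risk surface.
    """
    if samples.rr is None:
        raise ValueError("DIC needs stored relative-risk draws")
    e = compute_expected_counts(panel)
    rr_draws = samples.rr.reshape(-1, samples.N, samples.T)
    dev = np.empty(rr_draws.shape[0])
    for k in range(rr_draws.shape[0]):
        dev[k] = -2.0 * panel_loglik(panel, e, rr_draws[k])
    if not np.all(np.isfinite(dev)):
        bad = int(np.argmax(~np.isfinite(dev)))
        raise ValueError(f"non-finite deviance at draw {bad}")
    dbar = float(dev.mean())
    d_hat = -2.0 * panel_loglik(panel, e, relative_risk(samples.mean_draw(), panel))
    p_d = dbar - d_hat
    return FitDiagnostics(dbar=dbar, d_hat=d_hat, p_d=p_d, dic=dbar + p_d,
                          rhat=rhat_table(samples, include_fields=include_field_rhat))


def exceedance_probabilities(samples: PosteriorSamples, threshold: float = 1.0) -> np.ndarray:
    """P(RR_it > threshold | data) per area-year, shape (N, T)."""
    if samples.rr is None:
        raise ValueError("exceedance needs stored relative-risk draws")
    return (samples.rr.reshape(-1, samples.N, samples.T) > threshold).mean(axis=0)


def exceedance_probability(samples: PosteriorSamples, area: str, year: int,
                           threshold: float = 1.0) -> float:
    i = samples.area_ids.index(area)
    t = samples.years.index(year)
    return float(exceedance_probabilities(samples, threshold)[i, t])


def sign_probability(samples: PosteriorSamples, param: str,
                     direction: str = "positive") -> tuple[float, bool]:
    """Posterior probability that a parameter has the stated sign.

    Returns (probability, relevance flag); the flag records whether the
    probability exceeds the 90% reporting rule.  It is a flag, never a
    filter.
    """
    x = samples.get(param)
    if direction == "positive":
        p = float((x > 0).mean())
    elif direction == "negative":
        p = float((x < 0).mean())
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    return p, p > SIGN_RELEVANCE


def covariate_effect(beta: float, delta_x: float) -> tuple[float, int]:
    """Multiplicative relative-risk factor exp(beta * delta_x) for a covariate
    change of ``delta_x`` units, and the percent change rounded to an integer
    for reporting."""
    factor = float(np.exp(beta * delta_x))
    return factor, int(round((factor - 1.0) * 100.0))


def differential_trends(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-area posterior summary of the differential trend delta_i and the
    local trend gamma + delta_i, with a sign classification by posterior mean."""
    rows = []
    g = samples.get("gamma")
    for i, area in enumerate(samples.area_ids):
        d = samples.get(f"delta[{i + 1}]")
        local = g + d
        lo, hi = np.percentile(d, [2.5, 97.5])
        llo, lhi = np.percentile(local, [2.5, 97.5])
        rows.append({"area": area,
                     "delta_mean": float(d.mean()),
                     "delta_ci2.5": float(lo), "delta_ci97.5": float(hi),
                     "local_trend_mean": float(local.mean()),
                     "local_trend_ci2.5": float(llo), "local_trend_ci97.5": float(lhi),
                     "trend_above_mean": bool(d.mean() > 0)})
    return pd.DataFrame(rows)


def relative_risk_table(samples: PosteriorSamples, threshold: float = 1.0) -> pd.DataFrame:
    """Area-year table of posterior RR mean, 95% CrI and exceedance probability."""
    if samples.rr is None:
        raise ValueError("needs stored relative-risk draws")
    rr = samples.rr.reshape(-1, samples.N, samples.T)
    exc = exceedance_probabilities(samples, threshold)
    lo = np.percentile(rr, 2.5, axis=0)
    hi = np.percentile(rr, 97.5, axis=0)
    mean = rr.mean(axis=0)
    rows = []
    for i, area in enumerate(samples.area_ids):
        for t, year in enumerate(samples.years):
            rows.append({"area": area, "year": year, "rr_mean": mean[i, t],
                         "rr_ci2.5": lo[i, t], "rr_ci97.5": hi[i, t],
                         "exceedance_prob": exc[i, t]})
    return pd.DataFrame(rows)


def result_tables(samples: PosteriorSamples, panel: ArealPanel,
                  graph: AdjacencyGraph | None = None,
                  moran_include_self_lag: bool = False) -> dict[str, pd.DataFrame]:
    """Assemble the four standard output tables (consumed by panel I/O)."""
    from .residuals import fitted_values, moran_sti, residuals

    if samples.n_draws == 0:
        raise ValueError("refusing to summarize an empty posterior")
    tables = {
        "parameter_summary": summary_table(samples),
        "relative_risk": relative_risk_table(samples),
        "trends": differential_trends(samples),
    }
    diag = dic(samples, panel)
    rows = [("dic", diag.dic), ("dbar", diag.dbar), ("pd", diag.p_d)]
    rows += [(f"rhat_{k}", v) for k, v in rhat_table(samples, include_fields=False).items()]
    if graph is not None and panel.T >= 2:
        res = residuals(panel, fitted_values(samples, panel))
        m = moran_sti(res, graph, include_self_lag=moran_include_self_lag)
        rows += [("moran_sti", m.value), ("moran_self_lag", float(m.include_self_lag))]
    tables["diagnostics"] = pd.DataFrame(rows, columns=["name", "value"])
    return tables


def prior_sensitivity(panel: ArealPanel, graph: AdjacencyGraph, base: PriorSpec,
                      alternates: list[PriorSpec], config: MCMCConfig,
                      variant: str = "full") -> pd.DataFrame:
    """Refit under alternate priors and compare DIC, posterior means and RR.

    Returns one row per prior spec with its DIC, the fixed-effect posterior
    means, and the maximum absolute difference of the area-year RR means
    relative to the base fit.  A failed fit produces a row with the failure
    noted instead of aborting the whole table.
    """
    if not alternates:
        raise ValueError("need at least one alternate prior")
    rows = []
    base_rr = None
    for tag, spec in [("base", base)] + [(f"alt{k + 1}", s) for k, s in enumerate(alternates)]:
        row: dict = {"spec": tag, "coef_precision": spec.coef_precision,
                     "variance_prior": spec.variance_prior,
                     "hyper_shape": spec.hyper_shape, "hyper_rate": spec.hyper_rate}
        try:
            fit = run_chains(panel, graph, prior=spec, config=config, variant=variant)
            diag = dic(fit, panel)
            row["dic"] = diag.dic
            for p in ("alpha", "gamma") + (("beta_thi", "beta_ebf") if variant == "full" else ()):
                row[f"mean_{p}"] = float(fit.get(p).mean())
            rr = fit.rr_mean()
            if base_rr is None:
                base_rr = rr
                row["max_abs_rr_diff"] = 0.0
            else:
                row["max_abs_rr_diff"] = float(np.abs(rr - base_rr).max())
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - partial table contract
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
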