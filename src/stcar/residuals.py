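"""Fitted values, residuals and the space-time Moran index.

The index blends Moran's I spatial cross-products with a Durbin-Watson-style
one-period temporal lag: for residuals y_it with grand mean ybar,

    MoranSTI = (NT - N) * sum_{t=2..T} sum_i sum_j w_ij (y_it - ybar)(y_{j,t-1} - ybar)
               / ( [sum_{t=2..T} sum_i sum_j w_ij] * [sum_{t,i} (y_it - ybar)^2] )

with temporally invariant binary contiguity weights (not row-standardized).
By default the self-lag pair (area i at t with itself at t-1) is excluded,
matching a strictly neighbor-based reading; ``include_self_lag=True`` sets
w_ii = 1 inside this computation only (the Durbin-Watson flavor).  Values
near 0 indicate space-time randomness of the residual field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcmc import PosteriorSamples
from .model import compute_expected_counts
from .panel import AdjacencyGraph, ArealPanel


@dataclass
class ResidualField:
    """Residuals y_it = O_it - fitted_it, with their grand mean over all N*T cells."""

    y: np.ndarray
    y_bar: float


@dataclass
class MoranSTIResult:
    value: float
    include_self_lag: bool


def fitted_values(samples: PosteriorSamples, panel: ArealPanel) -> np.ndarray:
    """Fitted surface E_it times the posterior-mean relative risk, shape (N, T)."""
    e = compute_expected_counts(panel)
    return e.e * samples.rr_mean()


def residuals(panel: ArealPanel, fitted: np.ndarray) -> ResidualField:
    """Observed minus fitted counts, plus the grand mean of the residuals."""
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != panel.counts.shape:
        raise ValueError(f"fitted shape {fitted.shape} does not match panel "
                         f"{panel.counts.shape}")
    y = panel.counts - fitted
    return ResidualField(y=y, y_bar=float(y.mean()))


def moran_sti(res: ResidualField, graph: AdjacencyGraph,
              include_self_lag: bool = False) -> MoranSTIResult:
    """Space-time Moran autocorrelation of a residual field on a contiguity graph."""
    y = np.asarray(res.y, dtype=float)
    n, t = y.shape
    if t < 2:
        raise ValueError("space-time index undefined for a single time point")
    if graph.n_nodes != n:
        raise ValueError("graph size does not match residual field")
    if graph.n_edges == 0 and not include_self_lag:
        raise ValueError("graph has no edges")
    z = y - res.y_bar
    ss = float(np.sum(z * z))
    if ss == 0:
        raise ValueError("constant residuals: zero variance, index undefined")
    w = graph.weights.copy()
    if include_self_lag:
        w = w + np.eye(n)
    # numerator: sum over t >= 2 of z_t' W z_{t-1}
    num = float(np.sum(z[:, 1:] * (w @ z[:, :-1])))
    w_sum = float(w.sum()) * (t - 1)
    value = (n * t - n) * num / (w_sum * ss)
    return MoranSTIResult(value=value, include_self_lag=include_self_lag)
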