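"""Multi-chain Metropolis-within-Gibbs sampler for the space-time CAR model.

Non-conjugate blocks (intercept, slopes, trend, and each random-effect
component) move by symmetric random-walk Metropolis; the random-effect
precisions have conjugate Gamma full conditionals and are Gibbs-sampled.
ICAR fields are updated one independent set at a time (a greedy graph
coloring), which lets the per-area accept/reject decisions be vectorized
while remaining exactly the single-site kernel: areas within a color class
share no edge, so no update in the class reads another's proposal.

Identification: the flat direction of the intrinsic CAR (a constant shift of
the whole field) is confounded with the intercept (spatial field) or the
mean trend (differential-trend field).  After every sweep the field mean is
subtracted and absorbed into the corresponding fixed effect, which leaves
the linear predictor — and hence the posterior — untouched.

Proposal scales adapt by Robbins-Monro during burn-in only (targeting ~0.44
acceptance) and are frozen afterwards, preserving ergodicity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ParameterDraw, PriorSpec, compute_expected_counts
from .panel import AdjacencyGraph, ArealPanel

_TARGET_ACCEPT = 0.44


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults mirror a long production run (3 chains of 500,000 iterations,
    50,000 burn-in); tests and examples pass much shorter budgets.
    """

    n_chains: int = 3
    n_iterations: int = 500_000
    n_burnin: int = 50_000
    thin: int = 10
    seed: int = 0
    adapt: bool = True
    initial_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least 1 chain")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("burn-in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iterations - self.n_burnin) // self.thin < 1:
            raise ValueError("no draws would be retained")


def update_precision(field_values: np.ndarray, kind: str, graph: AdjacencyGraph,
                     spec: PriorSpec, rng: np.random.Generator) -> float:
    """Gibbs update of one random-effect variance from its conjugate posterior.

    With a Gamma(a, b) prior on the precision, the full conditional is
    Gamma(a + n*/2, b + q/2) where for an ICAR field q is the pairwise
    difference energy over edges and n* = N - c (c connected components);
    for an iid field q is the sum of squares and n* = N.  Returns the
    sampled variance (1/precision).
    """
    field_values = np.asarray(field_values, dtype=float)
    if kind == "icar":
        if field_values.shape != (graph.n_nodes,):
            raise ValueError("field dimension does not match graph")
        i, j = graph.edges[:, 0], graph.edges[:, 1]
        d = field_values[i] - field_values[j]
        q = float(d @ d)
        nstar = graph.n_nodes - graph.n_components
    elif kind == "iid":
        q = float(field_values @ field_values)
        nstar = field_values.size
    else:
        raise ValueError(f"unknown field kind {kind!r}")
    shape = spec.hyper_shape + nstar / 2.0
    rate = spec.hyper_rate + q / 2.0
    prec = rng.gamma(shape, 1.0 / rate)
    return float(1.0 / prec)


def conjugate_precision_posterior(field_values: np.ndarray, kind: str,
                                  graph: AdjacencyGraph, spec: PriorSpec) -> tuple[float, float]:
    """(shape, rate) of the Gamma full conditional used by :func:`update_precision`."""
    field_values = np.asarray(field_values, dtype=float)
    if kind == "icar":
        i, j = graph.edges[:, 0], graph.edges[:, 1]
        d = field_values[i] - field_values[j]
        q, nstar = float(d @ d), graph.n_nodes - graph.n_components
    elif kind == "iid":
        q, nstar = float(field_values @ field_values), field_values.size
    else:
        raise ValueError(f"unknown field kind {kind!r}")
    return spec.hyper_shape + nstar / 2.0, spec.hyper_rate + q / 2.0


class _FitContext:
    """Precomputed, immutable quantities shared by every sweep."""

    def __init__(self, panel: ArealPanel, graph: AdjacencyGraph, variant: str):
        if graph.n_nodes != panel.N:
            raise ValueError("graph size does not match panel")
        if list(graph.labels) != list(panel.area_ids):
            raise ValueError("graph node order does not match panel area order")
        self.N, self.T = panel.N, panel.T
        self.O = panel.counts.astype(float)
        self.E = compute_expected_counts(panel).e
        x_thi = panel.thi - panel.thi.mean()
        x_ebf = panel.ebf - panel.ebf.mean()
        t_c = panel.centered_time()
        self.x_thi = x_thi
        self.x_ebf2d = np.broadcast_to(x_ebf[:, None], (self.N, self.T)).copy()
        self.t_c = t_c
        self.t_c2d = np.broadcast_to(t_c[None, :], (self.N, self.T)).copy()
        self.O_sum = float(self.O.sum())
        self.O_row = self.O.sum(axis=1)
        self.O_t = self.O @ t_c
        self.W = graph.weights
        self.deg = graph.degrees
        self.colors = graph.coloring()
        self.all_idx = np.arange(self.N)
        self.nstar = graph.n_nodes - graph.n_components
        self.graph = graph
        self.variant = variant
        if graph.n_components > 1:
            warnings.warn(
                f"adjacency graph has {graph.n_components} components; "
                "ICAR rank and recentering use the component count", stacklevel=2)


def _init_state(ctx: _FitContext, rng: np.random.Generator,
                prior_only: bool, fix_random_effects: bool) -> dict:
    n = ctx.N
    st = {
        "alpha": 0.5 * rng.standard_normal() if not prior_only else 0.0,
        "beta_thi": 0.05 * rng.standard_normal(),
        "beta_ebf": 0.05 * rng.standard_normal(),
        "gamma": 0.05 * rng.standard_normal(),
        "u": rng.normal(0.0, 0.1, n),
        "v": rng.normal(0.0, 0.1, n),
        "delta": rng.normal(0.0, 0.1, n),
        "s2u": 0.01 * np.exp(0.5 * rng.standard_normal()),
        "s2v": 0.01 * np.exp(0.5 * rng.standard_normal()),
        "s2d": 0.01 * np.exp(0.5 * rng.standard_normal()),
        "nonfinite": 0,
    }
    if ctx.variant == "no_covariates":
        st["beta_thi"] = st["beta_ebf"] = 0.0
    if fix_random_effects:
        st["u"][:] = 0.0
        st["v"][:] = 0.0
        st["delta"][:] = 0.0
    else:
        st["u"] -= st["u"].mean()
        st["delta"] -= st["delta"].mean()
    return st


def _eta(st: dict, ctx: _FitContext) -> np.ndarray:
    return (st["alpha"] + st["u"][:, None] + st["v"][:, None]
            + st["beta_thi"] * ctx.x_thi + st["beta_ebf"] * ctx.x_ebf2d
            + (st["gamma"] + st["delta"][:, None]) * ctx.t_c2d)


def _scalar_step(st, ctx, mu, name, Z, tau, scale, rng, prior_only):
    d = scale * rng.standard_normal()
    cur = st[name]
    if prior_only:
        dll = 0.0
        de = None
    elif Z is None:  # intercept: uniform shift
        dll = d * ctx.O_sum - np.expm1(d) * mu.sum()
    else:
        de = d * Z
        dll = d * np.vdot(ctx.O, Z) - float(np.sum(mu * np.expm1(de)))
    dlp = 0.0 if tau is None else -0.5 * tau * ((cur + d) ** 2 - cur**2)
    ratio = dll + dlp
    if not np.isfinite(ratio):
        st["nonfinite"] += 1
        return False
    if np.log(rng.random()) < ratio:
        st[name] = cur + d
        if not prior_only:
            mu *= np.exp(d) if Z is None else np.exp(de)
        return True
    return False


def _field_step(st, ctx, mu, fname, kind, s2key, scale, rng, prior_only):
    """One sweep over a random-effect field; returns acceptance fraction."""
    f = st[fname]
    n = ctx.N
    d = scale * rng.standard_normal(n)
    logu = np.log(rng.random(n))
    s2 = st[s2key]
    groups = ctx.colors if kind == "icar" else [ctx.all_idx]
    time_field = fname == "delta"
    n_acc = 0
    for idx in groups:
        di = d[idx]
        fi = f[idx]
        if prior_only:
            dll = np.zeros(len(idx))
            em = None
        elif time_field:
            em = np.expm1(np.outer(di, ctx.t_c))
            dll = di * ctx.O_t[idx] - np.sum(mu[idx] * em, axis=1)
        else:
            e1 = np.expm1(di)
            dll = di * ctx.O_row[idx] - e1 * mu[idx].sum(axis=1)
            em = None
        if kind == "icar":
            s = ctx.W[idx] @ f
            dq = ctx.deg[idx] * ((fi + di) ** 2 - fi**2) - 2.0 * s * di
            dlp = -0.5 * dq / s2
        else:
            dlp = -0.5 * ((fi + di) ** 2 - fi**2) / s2
        ratio = dll + dlp
        bad = ~np.isfinite(ratio)
        if bad.any():
            st["nonfinite"] += int(bad.sum())
            ratio = np.where(bad, -np.inf, ratio)
        acc = logu[idx] < ratio
        if acc.any():
            sel = idx[acc]
            f[sel] += di[acc]
            if not prior_only:
                if time_field:
                    mu[sel] *= em[acc] + 1.0
                else:
                    mu[sel] *= np.exp(di[acc])[:, None]
        n_acc += int(acc.sum())
    return n_acc / n


def _uniform_sigma_step(st, ctx, s2key, q, nstar, upper, rng):
    """Metropolis step on log(sigma^2) under a Uniform(0, upper) prior on sigma."""
    x = np.log(st[s2key])

    def logp(xv):
        if np.exp(0.5 * xv) >= upper:
            return -np.inf
        return (0.5 - nstar / 2.0) * xv - 0.5 * q * np.exp(-xv)

    prop = x + 0.8 * rng.standard_normal()
    if np.log(rng.random()) < logp(prop) - logp(x):
        st[s2key] = float(np.exp(prop))


_SCALAR_BLOCKS = ("alpha", "beta_thi", "beta_ebf", "gamma")
_FIELD_BLOCKS = ("u", "v", "delta")


def _run_single_chain(ctx: _FitContext, spec: PriorSpec, config: MCMCConfig,
                      rng: np.random.Generator, prior_only: bool,
                      fix_random_effects: bool) -> dict:
    st = _init_state(ctx, rng, prior_only, fix_random_effects)
    mu = None if prior_only else ctx.E * np.exp(_eta(st, ctx))

    scalar_names = list(_SCALAR_BLOCKS)
    if ctx.variant == "no_covariates":
        scalar_names = ["alpha", "gamma"]
    if prior_only:
        scalar_names = [b for b in scalar_names if b != "alpha"]
    field_names = [] if fix_random_effects else list(_FIELD_BLOCKS)

    tau = spec.coef_precision
    scalar_meta = {"alpha": (None, None), "beta_thi": (ctx.x_thi, tau),
                   "beta_ebf": (ctx.x_ebf2d, tau), "gamma": (ctx.t_c2d, tau)}
    scales = {b: config.initial_scale for b in scalar_names + field_names}

    n_keep = (config.n_iterations - config.n_burnin) // config.thin
    kept_scalars = {b: np.empty(n_keep) for b in
                    scalar_names + (["alpha"] if prior_only and "alpha" not in scalar_names else [])}
    for b in ("alpha", "beta_thi", "beta_ebf", "gamma"):
        kept_scalars.setdefault(b, np.zeros(n_keep))
    kept_s2 = {k: np.empty(n_keep) for k in ("s2u", "s2v", "s2d")}
    kept_u = np.empty((n_keep, ctx.N))
    kept_v = np.empty((n_keep, ctx.N))
    kept_delta = np.empty((n_keep, ctx.N))
    kept_rr = None if prior_only else np.empty((n_keep, ctx.N, ctx.T))

    acc_post = {b: 0 for b in scalar_names + field_names}
    n_post = 0
    k_out = 0
    with np.errstate(over="ignore", under="ignore"):
        for it in range(config.n_iterations):
            sweep_acc = {}
            for b in scalar_names:
                Z, t_prec = scalar_meta[b]
                sweep_acc[b] = float(_scalar_step(
                    st, ctx, mu, b, Z, t_prec, scales[b], rng, prior_only))
            for b in field_names:
                kind = "iid" if b == "v" else "icar"
                s2key = {"u": "s2u", "v": "s2v", "delta": "s2d"}[b]
                sweep_acc[b] = _field_step(
                    st, ctx, mu, b, kind, s2key, scales[b], rng, prior_only)
            if field_names and not prior_only:
                st["s2u"] = update_precision(st["u"], "icar", ctx.graph, spec, rng) \
                    if spec.variance_prior == "gamma" else st["s2u"]
                st["s2v"] = update_precision(st["v"], "iid", ctx.graph, spec, rng) \
                    if spec.variance_prior == "gamma" else st["s2v"]
                st["s2d"] = update_precision(st["delta"], "icar", ctx.graph, spec, rng) \
                    if spec.variance_prior == "gamma" else st["s2d"]
                if spec.variance_prior == "uniform_sigma":
                    from .model import icar_quadratic
                    _uniform_sigma_step(st, ctx, "s2u", icar_quadratic(st["u"], ctx.graph),
                                        ctx.nstar, spec.sigma_upper, rng)
                    _uniform_sigma_step(st, ctx, "s2v", float(st["v"] @ st["v"]),
                                        ctx.N, spec.sigma_upper, rng)
                    _uniform_sigma_step(st, ctx, "s2d", icar_quadratic(st["delta"], ctx.graph),
                                        ctx.nstar, spec.sigma_upper, rng)
            if field_names:
                # absorb the CAR flat direction into the paired fixed effect
                m = st["u"].mean()
                st["u"] -= m
                st["alpha"] += m
                md = st["delta"].mean()
                st["delta"] -= md
                st["gamma"] += md
            if config.adapt and it < config.n_burnin:
                step = (it + 1.0) ** -0.6
                for b, a in sweep_acc.items():
                    scales[b] *= np.exp(step * (a - _TARGET_ACCEPT))
            if it >= config.n_burnin:
                n_post += 1
                for b, a in sweep_acc.items():
                    acc_post[b] += a
                if (it - config.n_burnin) % config.thin == config.thin - 1:
                    for b in kept_scalars:
                        kept_scalars[b][k_out] = st.get(b, 0.0)
                    kept_s2["s2u"][k_out] = st["s2u"]
                    kept_s2["s2v"][k_out] = st["s2v"]
                    kept_s2["s2d"][k_out] = st["s2d"]
                    kept_u[k_out] = st["u"]
                    kept_v[k_out] = st["v"]
                    kept_delta[k_out] = st["delta"]
                    if kept_rr is not None:
                        kept_rr[k_out] = mu / ctx.E
                    k_out += 1
    return {
        "scalars": kept_scalars, "s2": kept_s2, "u": kept_u, "v": kept_v,
        "delta": kept_delta, "rr": kept_rr,
        "acceptance": {b: acc_post[b] / max(n_post, 1) for b in acc_post},
        "scales": scales, "nonfinite": st["nonfinite"],
    }


@dataclass
class PosteriorSamples:
    """Multi-chain draw store feeding every posterior summary.

    Scalar parameters live in ``scalars`` as (chains, kept) arrays; the three
    random-effect fields as (chains, kept, N); the derived relative-risk
    surface as (chains, kept, N, T).  Names accepted by :meth:`get` /
    :meth:`chains` are ``alpha``, ``beta_thi``, ``beta_ebf``, ``gamma``,
    ``sigma2_u``, ``sigma2_v``, ``sigma2_delta``, ``u[k]``, ``v[k]``,
    ``delta[k]`` and ``rr[i,t]`` with 1-based indices.
    """

    area_ids: list[str]
    years: list[int]
    variant: str
    scalars: dict[str, np.ndarray]
    u: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    rr: np.ndarray | None
    acceptance: list[dict[str, float]]
    config: MCMCConfig
    prior: PriorSpec

    @property
    def n_chains(self) -> int:
        return self.u.shape[0]

    @property
    def n_kept(self) -> int:
        return self.u.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_kept

    @property
    def N(self) -> int:
        return len(self.area_ids)

    @property
    def T(self) -> int:
        return len(self.years)

    def param_names(self, include_rr: bool = False) -> list[str]:
        names = ["alpha"]
        if self.variant == "full":
            names += ["beta_thi", "beta_ebf"]
        names += ["gamma", "sigma2_u", "sigma2_v", "sigma2_delta"]
        names += [f"u[{k + 1}]" for k in range(self.N)]
        names += [f"v[{k + 1}]" for k in range(self.N)]
        names += [f"delta[{k + 1}]" for k in range(self.N)]
        if include_rr and self.rr is not None:
            names += [f"rr[{i + 1},{t + 1}]" for i in range(self.N) for t in range(self.T)]
        return names

    def chains(self, name: str) -> np.ndarray:
        """Per-chain draws of one parameter, shape (n_chains, n_kept)."""
        if name in self.scalars:
            return self.scalars[name]
        if name.startswith("rr[") and name.endswith("]"):
            if self.rr is None:
                raise KeyError("relative-risk draws were not stored for this run")
            i, t = (int(s) for s in name[3:-1].split(","))
            return self.rr[:, :, i - 1, t - 1]
        for fname, arr in (("u", self.u), ("v", self.v), ("delta", self.delta)):
            if name.startswith(fname + "[") and name.endswith("]"):
                return arr[:, :, int(name[len(fname) + 1:-1]) - 1]
        raise KeyError(f"unknown parameter {name!r}")

    def get(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter across chains (1-D)."""
        return self.chains(name).reshape(-1)

    def mean_draw(self) -> ParameterDraw:
        """Posterior means of all parameters, assembled into one state."""
        g = self.get
        return ParameterDraw(
            alpha=float(g("alpha").mean()),
            beta_thi=float(g("beta_thi").mean()) if self.variant == "full" else 0.0,
            beta_ebf=float(g("beta_ebf").mean()) if self.variant == "full" else 0.0,
            gamma=float(g("gamma").mean()),
            u=self.u.reshape(-1, self.N).mean(axis=0),
            v=self.v.reshape(-1, self.N).mean(axis=0),
            delta=self.delta.reshape(-1, self.N).mean(axis=0),
            sigma2_u=float(g("sigma2_u").mean()),
            sigma2_v=float(g("sigma2_v").mean()),
            sigma2_delta=float(g("sigma2_delta").mean()),
        )

    def rr_mean(self) -> np.ndarray:
        """Posterior-mean relative-risk surface, shape (N, T)."""
        if self.rr is None:
            raise ValueError("relative-risk draws were not stored for this run")
        return self.rr.reshape(-1, self.N, self.T).mean(axis=0)

    def to_dir(self, path: str | Path) -> None:
        """Write one CSV of draws per chain plus a metadata JSON."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        names = self.param_names(include_rr=self.rr is not None)
        for c in range(self.n_chains):
            cols = {}
            for nm in names:
                cols[nm] = self.chains(nm)[c]
            pd.DataFrame(cols).to_csv(out / f"chain_{c + 1}.csv", index=False)
        meta = {"area_ids": self.area_ids, "years": self.years, "variant": self.variant,
                "n_chains": self.n_chains, "config": asdict(self.config),
                "prior": asdict(self.prior), "acceptance": self.acceptance}
        (out / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "PosteriorSamples":
        out = Path(path)
        meta = json.loads((out / "meta.json").read_text())
        n_chains = meta["n_chains"]
        frames = [pd.read_csv(out / f"chain_{c + 1}.csv") for c in range(n_chains)]
        n = len(meta["area_ids"])
        t = len(meta["years"])
        variant = meta["variant"]
        k = len(frames[0])

        def stack(name):
            return np.stack([f[name].to_numpy() for f in frames])

        scalar_names = ["alpha", "gamma", "sigma2_u", "sigma2_v", "sigma2_delta"]
        if variant == "full":
            scalar_names += ["beta_thi", "beta_ebf"]
        scalars = {nm: stack(nm) for nm in scalar_names}
        u = np.stack([np.column_stack([f[f"u[{i + 1}]"] for i in range(n)]) for f in frames])
        v = np.stack([np.column_stack([f[f"v[{i + 1}]"] for i in range(n)]) for f in frames])
        delta = np.stack([np.column_stack([f[f"delta[{i + 1}]"] for i in range(n)]) for f in frames])
        rr = None
        if f"rr[1,1]" in frames[0].columns:
            rr = np.empty((n_chains, k, n, t))
            for c, f in enumerate(frames):
                for i in range(n):
                    for tt in range(t):
                        rr[c, :, i, tt] = f[f"rr[{i + 1},{tt + 1}]"]
        return cls(area_ids=meta["area_ids"], years=meta["years"], variant=variant,
                   scalars=scalars, u=u, v=v, delta=delta, rr=rr,
                   acceptance=meta.get("acceptance", []),
                   config=MCMCConfig(**meta["config"]),
                   prior=PriorSpec(**meta["prior"]))


def run_chains(panel: ArealPanel, graph: AdjacencyGraph,
               prior: PriorSpec | None = None, config: MCMCConfig | None = None,
               variant: str = "full", prior_only: bool = False,
               fix_random_effects: bool = False) -> PosteriorSamples:
    """Fit the model by ``n_chains`` independent MCMC runs.

    Parameters
    ----------
    variant
        ``"full"`` includes both covariate slopes; ``"no_covariates"`` fixes
        them at zero and skips their updates (the covariate-free comparison
        model).
    prior_only
        Sample the prior instead of the posterior: likelihood terms are
        switched off, the (improper-flat) intercept is held fixed, and the
        random-effect variances are frozen at their initial values.  Used to
        validate the sampler against known prior moments.
    fix_random_effects
        Hold all random effects at zero and skip their updates, leaving a
        low-dimensional GLM — the regime in which the posterior can be
        checked against brute-force grid integration.
    """
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    if variant not in ("full", "no_covariates"):
        raise ValueError("variant must be 'full' or 'no_covariates'")
    ctx = _FitContext(panel, graph, variant)
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [_run_single_chain(ctx, prior, config, np.random.default_rng(s),
                                prior_only, fix_random_effects)
              for s in children]

    scalar_names = ["alpha", "gamma"] + (["beta_thi", "beta_ebf"] if variant == "full" else [])
    scalars = {nm: np.stack([c["scalars"][nm] for c in chains]) for nm in scalar_names}
    scalars["sigma2_u"] = np.stack([c["s2"]["s2u"] for c in chains])
    scalars["sigma2_v"] = np.stack([c["s2"]["s2v"] for c in chains])
    scalars["sigma2_delta"] = np.stack([c["s2"]["s2d"] for c in chains])
    rr = None
    if chains[0]["rr"] is not None:
        rr = np.stack([c["rr"] for c in chains])
    return PosteriorSamples(
        area_ids=list(panel.area_ids), years=list(panel.years), variant=variant,
        scalars=scalars,
        u=np.stack([c["u"] for c in chains]),
        v=np.stack([c["v"] for c in chains]),
        delta=np.stack([c["delta"] for c in chains]),
        rr=rr,
        acceptance=[c["acceptance"] for c in chains],
        config=config, prior=prior)
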