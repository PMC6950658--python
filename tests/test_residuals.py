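import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stcar
from stcar import AdjacencyGraph, ResidualField, moran_sti
from stcar.residuals import fitted_values, residuals


def brute_force_moran_sti(y, w, include_self_lag=False):
    """Independent triple-loop reference implementation of the space-time index."""
    n, t = y.shape
    w = w.copy()
    if include_self_lag:
        w = w + np.eye(n)
    ybar = y.mean()
    num = 0.0
    wsum = 0.0
    for tt in range(1, t):
        for i in range(n):
            for j in range(n):
                num += w[i, j] * (y[i, tt] - ybar) * (y[j, tt - 1] - ybar)
                wsum += w[i, j]
    ss = ((y - ybar) ** 2).sum()
    return (n * t - n) * num / (wsum * ss)


def _random_graph(rng, n):
    while True:
        w = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
        w = w + w.T
        if w.sum() > 0:
            return AdjacencyGraph(labels=[str(i) for i in range(n)], weights=w)


def test_moran_hand_enumerated_example(pair_graph):
    y = np.array([[1.0, -1.0], [-1.0, 1.0]])
    res = ResidualField(y=y, y_bar=0.0)
    assert moran_sti(res, pair_graph).value == pytest.approx(0.5)
    r2 = moran_sti(res, pair_graph, include_self_lag=True)
    assert r2.value == pytest.approx(0.0)
    assert r2.include_self_lag is True


def test_moran_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(2, 7)
        t = rng.integers(2, 6)
        g = _random_graph(rng, int(n))
        y = rng.standard_normal((int(n), int(t)))
        res = ResidualField(y=y, y_bar=float(y.mean()))
        for self_lag in (False, True):
            got = moran_sti(res, g, include_self_lag=self_lag).value
            ref = brute_force_moran_sti(y, g.weights, self_lag)
            assert got == pytest.approx(ref, abs=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), c=st.floats(0.01, 100.0))
def test_moran_scale_invariance(seed, c):
    rng = np.random.default_rng(seed)
    g = _random_graph(rng, 5)
    y = rng.standard_normal((5, 4))
    base = moran_sti(ResidualField(y=y, y_bar=float(y.mean())), g).value
    for scale in (c, -c):
        scaled = scale * y
        got = moran_sti(ResidualField(y=scaled, y_bar=float(scaled.mean())), g).value
        assert got == pytest.approx(base, rel=1e-9, abs=1e-12)


def test_moran_degenerate_inputs(pair_graph):
    with pytest.raises(ValueError, match="single time"):
        moran_sti(ResidualField(y=np.ones((2, 1)), y_bar=1.0), pair_graph)
    with pytest.raises(ValueError, match="constant"):
        moran_sti(ResidualField(y=np.ones((2, 3)), y_bar=1.0), pair_graph)


def test_moran_iid_null_mean_matches_permutation_null():
    """Over iid residual fields the index centers on its permutation-null mean."""
    rng = np.random.default_rng(1)
    g = stcar.make_lattice_graph(2, 3)
    vals = []
    for _ in range(500):
        y = rng.standard_normal((6, 4))
        vals.append(moran_sti(ResidualField(y=y, y_bar=float(y.mean())), g).value)
    perm = []
    base = rng.standard_normal(24)
    for _ in range(500):
        y = rng.permutation(base).reshape(6, 4)
        perm.append(moran_sti(ResidualField(y=y, y_bar=float(y.mean())), g).value)
    se = np.sqrt(np.var(vals) / 500 + np.var(perm) / 500)
    assert abs(np.mean(vals) - np.mean(perm)) < 3 * se


def test_moran_detects_positive_spacetime_dependence():
    """Residuals built with strong positive lag-1 neighbor dependence yield a
    positive index nearly always."""
    rng = np.random.default_rng(2)
    g = stcar.make_lattice_graph(3, 4)
    wnorm = g.weights / np.maximum(g.degrees[:, None], 1)
    pos = 0
    for _ in range(500):
        y = np.empty((12, 5))
        y[:, 0] = rng.standard_normal(12)
        for _ in range(2):  # spatially smooth starting field
            y[:, 0] = 0.5 * y[:, 0] + 0.5 * wnorm @ y[:, 0]
        for t in range(1, 5):
            y[:, t] = 0.6 * y[:, t - 1] + 0.6 * wnorm @ y[:, t - 1] \
                + 0.05 * rng.standard_normal(12)
        if moran_sti(ResidualField(y=y, y_bar=float(y.mean())), g).value > 0:
            pos += 1
    assert pos >= 0.95 * 500


def test_residuals_hand_values(tiny_panel):
    fitted = np.zeros((2, 2))
    with pytest.raises(ValueError):
        residuals(tiny_panel, np.zeros((3, 3)))
    r = residuals(tiny_panel, tiny_panel.counts)
    np.testing.assert_array_equal(r.y, 0.0)
    assert r.y_bar == 0.0
    r2 = residuals(tiny_panel, fitted)
    np.testing.assert_array_equal(r2.y, tiny_panel.counts)
    assert r2.y_bar == pytest.approx(tiny_panel.counts.mean())


def test_fitted_values_degenerate_and_calibrated(fitted, default_panel):
    panel, _ = default_panel
    f = fitted_values(fitted, panel)
    assert np.all(f > 0)
    # converged fit reproduces the total count closely
    assert abs(f.sum() - panel.counts.sum()) / panel.counts.sum() < 0.05
    from conftest import make_samples
    unit = make_samples({"alpha": np.zeros((1, 150))}, rr=np.ones((1, 150, 2, 2)))
    import stcar.model as model
    tiny = stcar.ArealPanel(area_ids=["A", "B"], years=[2010, 2011],
                            counts=np.array([[1.0, 2.0], [3.0, 4.0]]),
                            populations=np.full((2, 2), 1000.0),
                            thi=np.full((2, 2), 30.0), ebf=np.array([60.0, 60.0]))
    np.testing.assert_allclose(fitted_values(unit, tiny),
                               model.compute_expected_counts(tiny).e)
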