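import numpy as np
import pandas as pd
import pytest

import stcar
from stcar.panel import PanelFormatError, PanelValidationError


def _frame(rows):
    return pd.DataFrame(rows, columns=["area_id", "year", "count", "population",
                                       "thi_rate", "ebf_pct"])


def test_read_minimal_panel(tmp_path):
    f = tmp_path / "p.csv"
    _frame([("A", 2010, 5, 1000, 30.0, 60.0), ("A", 2011, 6, 1000, 31.0, 60.0),
            ("B", 2010, 7, 2000, 40.0, 55.0), ("B", 2011, 8, 2000, 41.0, 55.0)]
           ).to_csv(f, index=False)
    p = stcar.read_panel(f)
    assert (p.N, p.T) == (2, 2)
    assert p.area_ids == ["A", "B"] and p.years == [2010, 2011]
    assert p.counts[1, 1] == 8 and p.ebf[1] == 55.0


@pytest.mark.parametrize("mutate, err", [
    (lambda rows: rows[:-1], PanelFormatError),                     # missing cell
    (lambda rows: [r[:2] + r[3:] for r in rows], PanelFormatError),  # fewer columns handled below
    (lambda rows: [("A", 2010, -5) + rows[0][3:]] + rows[1:], PanelValidationError),
    (lambda rows: [("A", 2010, 5, 0) + rows[0][4:]] + rows[1:], PanelValidationError),
    (lambda rows: [rows[0][:5] + (99.0,)] + rows[1:], PanelValidationError),  # ebf varies
])
def test_panel_rejects_invalid(tmp_path, mutate, err):
    rows = [("A", 2010, 5, 1000, 30.0, 60.0), ("A", 2011, 6, 1000, 31.0, 60.0),
            ("B", 2010, 7, 2000, 40.0, 55.0), ("B", 2011, 8, 2000, 41.0, 55.0)]
    bad = mutate(rows)
    f = tmp_path / "p.csv"
    if len(bad[0]) < 6:
        pd.DataFrame(bad).to_csv(f, index=False)
        with pytest.raises(PanelFormatError):
            stcar.read_panel(f)
    else:
        _frame(bad).to_csv(f, index=False)
        with pytest.raises((PanelFormatError, PanelValidationError)):
            stcar.read_panel(f)


def test_panel_roundtrip(tmp_path):
    graph = stcar.make_lattice_graph(3, 4)
    panel, _ = stcar.simulate_panel(graph, 4, stcar.SimulationParams(seed=5))
    f = tmp_path / "p.csv"
    stcar.write_panel(panel, f)
    back = stcar.read_panel(f)
    assert back.area_ids == panel.area_ids and back.years == panel.years
    for a, b in ((back.counts, panel.counts), (back.populations, panel.populations),
                 (back.thi, panel.thi), (back.ebf, panel.ebf)):
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_gal_roundtrip(tmp_path):
    graph = stcar.make_lattice_graph(4, 3)
    f = tmp_path / "g.gal"
    stcar.write_gal(graph, f)
    back = stcar.read_gal(f, n_expected=12)
    assert back.labels == graph.labels
    np.testing.assert_array_equal(back.weights, graph.weights)


def test_gal_two_node_path(tmp_path):
    f = tmp_path / "g.gal"
    f.write_text("2\nA 1\nB\nB 1\nA\n")
    g = stcar.read_gal(f)
    assert g.neighbor_lists() == {"A": ["B"], "B": ["A"]}


def test_gal_asymmetric_rejected(tmp_path):
    f = tmp_path / "g.gal"
    f.write_text("2\nA 1\nB\nB 0\n")
    with pytest.raises(ValueError, match="asymmetric"):
        stcar.read_gal(f)


def test_gal_node_count_mismatch(tmp_path):
    f = tmp_path / "g.gal"
    f.write_text("2\nA 1\nB\nB 1\nA\n")
    with pytest.raises(ValueError, match="expected"):
        stcar.read_gal(f, n_expected=5)


def _raw_thi(areas, years, base=20.0):
    rows = [(a, y, base + i + 0.1 * y) for i, a in enumerate(areas) for y in years]
    return pd.DataFrame(rows, columns=["area_id", "year", "thi_rate"])


def test_covariate_lag(tiny_panel):
    raw = _raw_thi(["A", "B"], range(2008, 2012))
    lag0 = stcar.apply_covariate_lag(tiny_panel, raw, lag=0)
    assert lag0.thi[0, 0] == pytest.approx(20.0 + 0.1 * 2010)
    lag1 = stcar.apply_covariate_lag(tiny_panel, raw, lag=1)
    # panel year 2010 must see the raw rate from 2009
    assert lag1.thi[0, 0] == pytest.approx(20.0 + 0.1 * 2009)
    assert lag1.thi[1, 1] == pytest.approx(21.0 + 0.1 * 2010)
    np.testing.assert_array_equal(lag1.counts, tiny_panel.counts)


def test_covariate_lag_missing_year(tiny_panel):
    raw = _raw_thi(["A", "B"], [2010, 2011])  # lacks 2009
    with pytest.raises(PanelFormatError, match="2009"):
        stcar.apply_covariate_lag(tiny_panel, raw, lag=1)


def test_write_results_roundtrip(tmp_path, fitted, default_panel, lattice34):
    panel, _ = default_panel
    tables = stcar.result_tables(fitted, panel, lattice34)
    assert len(tables["relative_risk"]) == panel.N * panel.T
    paths = stcar.write_results(tables, tmp_path / "out")
    assert set(paths) == {"parameter_summary", "relative_risk", "trends", "diagnostics"}
    back = stcar.read_results(tmp_path / "out")
    for name, df in tables.items():
        num = df.select_dtypes("number")
        np.testing.assert_allclose(back[name][num.columns].to_numpy(),
                                   num.to_numpy(), atol=1e-12)


def test_write_results_requires_all_tables(tmp_path):
    with pytest.raises(ValueError, match="missing"):
        stcar.write_results({"parameter_summary": pd.DataFrame()}, tmp_path)
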