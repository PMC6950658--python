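"""Reading and writing panels, GAL adjacency files, configs and result tables.

The canonical panel exchange format is a long CSV with columns
``area_id, year, count, population, thi_rate, ebf_pct`` (one row per
area-year).  Adjacency travels as a GAL spatial-weights file: a header line
with the node count, then for each node a ``label n_neighbors`` line followed
by a line listing its neighbors' labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import AdjacencyGraph, ArealPanel, PanelFormatError, PanelValidationError

PANEL_COLUMNS = ["area_id", "year", "count", "population", "thi_rate", "ebf_pct"]


def read_panel(path: str | Path) -> ArealPanel:
    """Read a long-format panel CSV into a validated :class:`ArealPanel`.

    Areas are ordered by first appearance in the file, years ascending.  The
    spatial-only covariate must repeat identically across each area's rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel CSV missing columns: {missing}")
    area_ids = list(dict.fromkeys(df["area_id"].astype(str)))
    years = sorted(df["year"].astype(int).unique())
    n, t = len(area_ids), len(years)
    if len(df) != n * t:
        raise PanelFormatError(
            f"incomplete panel: {len(df)} rows, expected {n} areas x {t} years = {n * t}"
        )
    key = df.set_index([df["area_id"].astype(str), df["year"].astype(int)])
    if key.index.has_duplicates:
        raise PanelFormatError("duplicate (area, year) rows")
    counts = np.empty((n, t))
    pops = np.empty((n, t))
    thi = np.empty((n, t))
    ebf = np.empty(n)
    for i, a in enumerate(area_ids):
        for j, y in enumerate(years):
            try:
                row = key.loc[(a, y)]
            except KeyError:
                raise PanelFormatError(f"incomplete panel: missing cell ({a}, {y})") from None
            counts[i, j] = row["count"]
            pops[i, j] = row["population"]
            thi[i, j] = row["thi_rate"]
        evals = np.unique(np.round(df.loc[df["area_id"].astype(str) == a, "ebf_pct"], 10))
        if len(evals) != 1:
            raise PanelValidationError(f"ebf_pct differs across years within area {a}")
        ebf[i] = evals[0]
    return ArealPanel(area_ids=area_ids, years=years, counts=counts,
                      populations=pops, thi=thi, ebf=ebf)


def write_panel(panel: ArealPanel, path: str | Path) -> None:
    rows = []
    for i, a in enumerate(panel.area_ids):
        for j, y in enumerate(panel.years):
            rows.append((a, y, int(panel.counts[i, j]), panel.populations[i, j],
                         panel.thi[i, j], panel.ebf[i]))
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)


def apply_covariate_lag(panel: ArealPanel, raw_thi: pd.DataFrame, lag: int) -> ArealPanel:
    """Replace the panel's space-time covariate with a lagged raw series.

    ``raw_thi`` is a long table with columns ``area_id, year, thi_rate``
    covering every (area, year - lag) the panel needs.  The returned panel's
    covariate at (i, y) equals the raw rate at (i, y - lag); counts and
    populations are unchanged.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    tab = raw_thi.set_index([raw_thi["area_id"].astype(str), raw_thi["year"].astype(int)])
    thi = np.empty((panel.N, panel.T))
    for i, a in enumerate(panel.area_ids):
        for j, y in enumerate(panel.years):
            try:
                thi[i, j] = tab.loc[(a, y - lag)]["thi_rate"]
            except KeyError:
                raise PanelFormatError(
                    f"raw covariate table missing ({a}, {y - lag}) needed for lag {lag}"
                ) from None
    return ArealPanel(area_ids=list(panel.area_ids), years=list(panel.years),
                      counts=panel.counts.copy(), populations=panel.populations.copy(),
                      thi=thi, ebf=panel.ebf.copy())


def read_gal(path: str | Path, n_expected: int | None = None,
             labels: list[str] | None = None) -> AdjacencyGraph:
    """Read a GAL spatial-weights file into a symmetric binary graph.

    Accepts the plain header (``n``) and the legacy 4-token header
    (``0 n shapefile key``).  Raises on asymmetric listings.  If ``labels`` is
    given, the result is permuted into that node order.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise PanelFormatError("empty GAL file")
    head = lines[0].split()
    n = int(head[1]) if len(head) > 1 and head[0] == "0" else int(head[0])
    if n_expected is not None and n != n_expected:
        raise ValueError(f"GAL declares {n} nodes, expected {n_expected}")
    node_labels: list[str] = []
    nbrs: dict[str, list[str]] = {}
    k = 1
    for _ in range(n):
        if k >= len(lines):
            raise PanelFormatError("GAL file truncated")
        lab, cnt = lines[k].split()[0], int(lines[k].split()[1])
        if cnt > 0:
            if k + 1 >= len(lines):
                raise PanelFormatError("GAL file truncated")
            listed = lines[k + 1].split()
            if len(listed) != cnt:
                raise PanelFormatError(f"node {lab}: {len(listed)} neighbors listed, header says {cnt}")
            k += 2
        else:
            listed = []
            k += 1
        node_labels.append(lab)
        nbrs[lab] = listed
    if len(set(node_labels)) != n:
        raise PanelFormatError("duplicate node labels in GAL file")
    idx = {a: i for i, a in enumerate(node_labels)}
    w = np.zeros((n, n))
    for a, lst in nbrs.items():
        for b in lst:
            if b not in idx:
                raise PanelFormatError(f"unknown neighbor label {b!r}")
            w[idx[a], idx[b]] = 1.0
    if not np.array_equal(w, w.T):
        bad = np.argwhere(w != w.T)
        a, b = node_labels[bad[0][0]], node_labels[bad[0][1]]
        raise ValueError(f"asymmetric GAL listing: {a} -> {b} without the reverse")
    graph = AdjacencyGraph(labels=node_labels, weights=w)
    if labels is not None:
        graph = graph.reordered([str(a) for a in labels])
    return graph


def write_gal(graph: AdjacencyGraph, path: str | Path) -> None:
    out = [str(graph.n_nodes)]
    nbrs = graph.neighbor_lists()
    for a in graph.labels:
        out.append(f"{a} {len(nbrs[a])}")
        if nbrs[a]:
            out.append(" ".join(nbrs[a]))
    Path(path).write_text("\n".join(out) + "\n")


@dataclass
class RunConfig:
    """Run configuration: priors, sampler settings, variant and covariate lag."""

    prior: "PriorSpec" = None  # type: ignore[assignment]
    mcmc: "MCMCConfig" = None  # type: ignore[assignment]
    lag: int = 1
    variant: str = "full"

    def __post_init__(self) -> None:
        from .mcmc import MCMCConfig
        from .model import PriorSpec

        if self.prior is None:
            self.prior = PriorSpec()
        if self.mcmc is None:
            self.mcmc = MCMCConfig()
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.variant not in ("no_covariates", "full"):
            raise ValueError("variant must be 'no_covariates' or 'full'")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        from .mcmc import MCMCConfig
        from .model import PriorSpec

        raw = json.loads(Path(path).read_text())
        return cls(prior=PriorSpec(**raw.get("prior", {})),
                   mcmc=MCMCConfig(**raw.get("mcmc", {})),
                   lag=raw.get("lag", 1), variant=raw.get("variant", "full"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"prior": asdict(self.prior), "mcmc": asdict(self.mcmc),
             "lag": self.lag, "variant": self.variant}, indent=2))


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write the result tables produced by :func:`stcar.analysis.result_tables`.

    Emits ``parameter_summary.csv``, ``relative_risk.csv``, ``trends.csv`` and
    ``diagnostics.csv`` under ``out_dir``.
    """
    expected = {"parameter_summary", "relative_risk", "trends", "diagnostics"}
    missing = expected - set(tables)
    if missing:
        raise ValueError(f"missing result tables: {sorted(missing)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in sorted(expected):
        p = out / f"{name}.csv"
        tables[name].to_csv(p, index=False)
        paths[name] = p
    return paths


def read_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = Path(out_dir)
    return {name: pd.read_csv(out / f"{name}.csv")
            for name in ("parameter_summary", "relative_risk", "trends", "diagnostics")}
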