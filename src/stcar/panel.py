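"""Areal panel and adjacency containers.

An :class:`ArealPanel` holds a complete N-areas x T-years panel of disease
counts ``O_it``, populations ``rho_it`` and two covariates: a space-time rate
(traumatic head injury hospitalizations per 100,000, already lagged) and a
spatial-only percentage (excess body fat, temporally constant).  An
:class:`AdjacencyGraph` holds the binary contiguity structure ``w_ij`` used by
the intrinsic CAR priors and by the space-time Moran residual index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


class PanelFormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class PanelValidationError(ValueError):
    """Raised when panel contents violate an invariant (negative counts, ...)."""


@dataclass
class ArealPanel:
    """Complete areal count panel over N areas and T years.

    Parameters
    ----------
    area_ids
        Ordered area labels, length N.
    years
        Ordered calendar years, length T, strictly increasing.  Model time is
        the 1-based position ``t = 1..T``; calendar years are labels only.
    counts
        Observed case counts ``O_it``, shape (N, T), non-negative integers.
    populations
        Person counts ``rho_it``, shape (N, T), positive.
    thi
        Space-time covariate (rate per 100,000), shape (N, T).  Expected to be
        the lag-applied value: the entry at year ``y`` is the raw rate at
        ``y - lag``.
    ebf
        Spatial-only covariate (percent), shape (N,), one value per area.
    """

    area_ids: list[str]
    years: list[int]
    counts: np.ndarray
    populations: np.ndarray
    thi: np.ndarray
    ebf: np.ndarray

    def __post_init__(self) -> None:
        self.area_ids = [str(a) for a in self.area_ids]
        self.years = [int(y) for y in self.years]
        self.counts = np.asarray(self.counts, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.thi = np.asarray(self.thi, dtype=float)
        self.ebf = np.asarray(self.ebf, dtype=float)
        self.validate()

    @property
    def N(self) -> int:
        return len(self.area_ids)

    @property
    def T(self) -> int:
        return len(self.years)

    def validate(self) -> None:
        n, t = len(self.area_ids), len(self.years)
        if n < 2:
            raise PanelValidationError("panel needs at least 2 areas")
        if t < 1:
            raise PanelValidationError("panel needs at least 1 year")
        if len(set(self.area_ids)) != n:
            raise PanelValidationError("duplicate area ids")
        if sorted(self.years) != self.years or len(set(self.years)) != t:
            raise PanelValidationError("years must be strictly increasing")
        for name, arr, shape in (
            ("counts", self.counts, (n, t)),
            ("populations", self.populations, (n, t)),
            ("thi", self.thi, (n, t)),
            ("ebf", self.ebf, (n,)),
        ):
            if arr.shape != shape:
                raise PanelValidationError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise PanelValidationError(f"{name} contains non-finite values")
        if np.any(self.counts < 0):
            raise PanelValidationError("counts must be non-negative")
        if np.any(self.counts != np.round(self.counts)):
            raise PanelValidationError("counts must be integers")
        if np.any(self.populations <= 0):
            raise PanelValidationError("populations must be positive")
        if np.any(self.thi < 0):
            raise PanelValidationError("thi rate must be non-negative")

    def centered_time(self) -> np.ndarray:
        """Model time centered at its midpoint: t - (T+1)/2 for t = 1..T."""
        return np.arange(1, self.T + 1, dtype=float) - (self.T + 1) / 2.0


@dataclass
class AdjacencyGraph:
    """Symmetric binary contiguity graph over the panel's areas.

    ``weights[i, j] = 1`` when areas i and j are neighbors; the diagonal is
    zero.  Node order must match the panel's area order.
    """

    labels: list[str]
    weights: np.ndarray
    # cached derived structure
    _edges: np.ndarray = field(init=False, repr=False)
    _components: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(a) for a in self.labels]
        w = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} does not match {n} labels")
        if not np.array_equal(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.all(np.isin(w, (0.0, 1.0))):
            raise ValueError("adjacency weights must be binary")
        self.weights = w
        iu, ju = np.nonzero(np.triu(w))
        self._edges = np.column_stack([iu, ju]).astype(int)
        _, self._components = connected_components(csr_matrix(w), directed=False)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def edges(self) -> np.ndarray:
        """(m, 2) array of undirected edges, each listed once with i < j."""
        return self._edges

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def component_labels(self) -> np.ndarray:
        return self._components

    @property
    def n_components(self) -> int:
        return int(self._components.max()) + 1 if self.n_nodes else 0

    def neighbor_lists(self) -> dict[str, list[str]]:
        return {
            self.labels[i]: [self.labels[j] for j in np.nonzero(self.weights[i])[0]]
            for i in range(self.n_nodes)
        }

    def coloring(self) -> list[np.ndarray]:
        """Partition nodes into independent sets (greedy graph coloring).

        Nodes within one set share no edge, so single-site Metropolis updates
        of an ICAR field can be performed simultaneously within a set.
        """
        g = self.to_networkx()
        colors = nx.greedy_color(g, strategy="largest_first")
        n_col = max(colors.values()) + 1 if colors else 0
        return [
            np.array([i for i in range(self.n_nodes) if colors[i] == c], dtype=int)
            for c in range(n_col)
        ]

    def laplacian(self) -> np.ndarray:
        return np.diag(self.degrees) - self.weights

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self._edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, labels: list[str] | None = None) -> "AdjacencyGraph":
        nodes = list(g.nodes())
        if labels is None:
            labels = [str(v) for v in nodes]
        idx = {v: k for k, v in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for a, b in g.edges():
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1.0
        return cls(labels=labels, weights=w)

    def reordered(self, labels: list[str]) -> "AdjacencyGraph":
        """Return the same graph with nodes permuted into ``labels`` order."""
        if sorted(labels) != sorted(self.labels):
            raise ValueError("label sets differ")
        perm = [self.labels.index(a) for a in labels]
        return AdjacencyGraph(labels=list(labels), weights=self.weights[np.ix_(perm, perm)])
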