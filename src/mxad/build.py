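"""Group-level covariance-layer construction and binarization.

Each layer's edges are partial correlations between every pair of
regions controlling for age and sex, computed as Pearson correlations of
covariate-residualized regional values across the subjects of one group.
Binary layers keep a fixed fraction of the strongest edges (proportional
thresholding) so that both layers and all groups are compared at
identical edge counts over the 2--30% density range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cohort import RegionalCohort, residualize

GRID_DENSITIES = tuple(round(0.02 + 0.01 * i, 2) for i in range(29))  # 2% .. 30%


@dataclass
class WeightedLayer:
    """Symmetric weighted adjacency (partial correlations), zero diagonal."""

    weights: np.ndarray
    layer_tag: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("diagonal must be zero (self-connections ignored)")
        if np.any(np.abs(w) > 1 + 1e-9):
            raise ValueError("correlation weights must lie in [-1, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryLayer:
    """Symmetric 0/1 adjacency at a fixed edge density."""

    adjacency: np.ndarray
    layer_tag: str
    density: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        n = a.shape[0]
        if self.density is None:
            self.density = self.n_edges / (n * (n - 1) / 2)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class WeightedMultiplex:
    """Two weighted layers over the same ordered node set."""

    layers: tuple[WeightedLayer, WeightedLayer]
    region_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a, b = self.layers
        if a.n_nodes != b.n_nodes:
            raise ValueError("layers must share the node set")
        if self.region_names is not None and len(self.region_names) != a.n_nodes:
            raise ValueError("region_names must match the node count")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes


@dataclass
class BinaryMultiplex:
    """Two density-matched binary layers."""

    layers: tuple[BinaryLayer, BinaryLayer]
    region_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a, b = self.layers
        if a.n_nodes != b.n_nodes:
            raise ValueError("layers must share the node set")
        if a.n_edges != b.n_edges:
            raise ValueError("layers must be density-matched (equal edge counts)")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def density(self) -> float:
        return self.layers[0].density


def partial_corr_layer(cohort: RegionalCohort, layer_tag: str | None = None) -> WeightedLayer:
    """Partial-correlation layer for one group's cohort.

    Residualizes the regional values on age and sex, then correlates
    every region pair (Pearson).  Diagonal is zeroed.
    """
    resid = residualize(cohort.values, cohort.age, cohort.sex)
    sd = resid.std(axis=0)
    dead = np.flatnonzero(sd < 1e-12)
    if dead.size:
        names = [cohort.region_names[j] for j in dead]
        raise ValueError(f"constant region(s) after residualization: {names}")
    corr = np.corrcoef(resid, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    corr = (corr + corr.T) / 2
    return WeightedLayer(corr, layer_tag or cohort.modality)


def _edge_order(weights: np.ndarray, ranking: str = "signed"):
    """Upper-triangle edges sorted by weight desc, ties by (i, j) lexicographic."""
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w = weights[iu, ju]
    key = np.abs(w) if ranking == "absolute" else w
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order], w[order]


def binarize_at_density(layer: WeightedLayer, density: float, ranking: str = "signed") -> BinaryLayer:
    """Keep exactly round(D * N(N-1)/2) strongest edges of the layer.

    Ranking is by signed weight (strongest positive correlations first)
    by default; ``ranking="absolute"`` ranks by magnitude.  Ties break by
    lexicographic node-pair order so the edge set is reproducible.
    """
    if not 0 < density < 1:
        raise ValueError("density must lie strictly between 0 and 1")
    n = layer.n_nodes
    n_pairs = n * (n - 1) // 2
    n_edges = int(round(density * n_pairs))
    if n_edges < 1:
        raise ValueError(f"density {density} keeps no edges for N={n}")
    ii, jj, ww = _edge_order(layer.weights, ranking)
    if ranking == "signed" and (ww[:n_edges] <= 0).any():
        warnings.warn(
            f"fewer than {n_edges} positive weights; negative-weight edges "
            "admitted by rank", stacklevel=2,
        )
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[:n_edges], jj[:n_edges]] = 1
    adj += adj.T
    return BinaryLayer(adj, layer.layer_tag, density=density)


def density_sweep(
    mx: WeightedMultiplex,
    d_min: float = 0.02,
    d_max: float = 0.30,
    step: float = 0.01,
    ranking: str = "signed",
) -> list[BinaryMultiplex]:
    """Binarize both layers at every density of the grid (default 2--30%, 1% steps)."""
    if not d_min < d_max:
        raise ValueError("d_min must be below d_max")
    n_steps = int(round((d_max - d_min) / step))
    densities = [round(d_min + k * step, 10) for k in range(n_steps + 1)]
    out = []
    for d in densities:
        layers = tuple(binarize_at_density(l, d, ranking) for l in mx.layers)
        out.append(BinaryMultiplex(layers, mx.region_names))
    return out


@dataclass
class SmallWorldResult:
    sigma: float
    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    connected: bool


def small_world_index(layer: BinaryLayer, n_random: int = 20, seed: int = 0) -> SmallWorldResult:
    """Small-world index sigma = (C/C_rand) / (L/L_rand).

    C is the mean clustering coefficient and L the characteristic path
    length (computed on the largest connected component if the graph is
    disconnected, with ``connected=False`` flagged); the reference values
    are means over ``n_random`` Maslov-Sneppen degree-preserving rewired
    graphs.
    """
    G = nx.from_numpy_array(np.asarray(layer.adjacency, dtype=int))
    comps = sorted(nx.connected_components(G), key=len, reverse=True)
    connected = len(comps) == 1
    if len(comps[0]) < 0.9 * layer.n_nodes:
        warnings.warn("largest component below 90% of nodes; sigma unreliable", stacklevel=2)

    def _stats(graph):
        c = nx.average_clustering(graph)
        giant = graph.subgraph(max(nx.connected_components(graph), key=len))
        l = nx.average_shortest_path_length(giant)
        return c, l

    C, L = _stats(G)
    rng = np.random.Generator(np.random.PCG64(seed))
    c_r, l_r = [], []
    n_edges = G.number_of_edges()
    for k in range(n_random):
        R = G.copy()
        nx.double_edge_swap(R, nswap=5 * n_edges, max_tries=100 * n_edges,
                            seed=int(rng.integers(2**31)))
        c, l = _stats(R)
        c_r.append(c)
        l_r.append(l)
    c_rand, l_rand = float(np.mean(c_r)), float(np.mean(l_r))
    sigma = (C / c_rand) / (L / l_rand) if c_rand > 0 else np.inf
    return SmallWorldResult(float(sigma), C, L, c_rand, l_rand, connected)


def save_layer(layer: WeightedLayer | BinaryLayer, path, region_names=None) -> None:
    """Write a labeled delimited matrix (TSV) for a layer."""
    import pandas as pd

    mat = layer.weights if isinstance(layer, WeightedLayer) else layer.adjacency
    names = list(region_names) if region_names is not None else list(range(mat.shape[0]))
    # %.17g is roundtrip-exact for float64, so reloaded metrics agree bitwise
    pd.DataFrame(mat, index=names, columns=names).to_csv(path, sep="\t", float_format="%.17g")


def load_weighted_layer(path, layer_tag: str) -> WeightedLayer:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return WeightedLayer(df.to_numpy(float), layer_tag)
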