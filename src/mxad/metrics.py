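"""Nodal multiplex network measures.

Weighted: overlapping strength s_i = s_i^[1] + s_i^[2], the sum of a
node's connectivity strength in both layers.

Binary (computed at matched densities):

* degree overlap d_i = sum_j a_ij^[1] a_ij^[2] — connections a node has
  in both layers simultaneously;
* multiplex participation p_i = (M/(M-1)) [1 - sum_a (k_i^[a]/o_i)^2] —
  evenness of a node's degree across the M=2 layers, 1 when the layer
  degrees are equal and nonzero, 0 when only one layer carries edges;
* multiplex clustering c_i — ratio of 2-triangles with a vertex in i
  (edge ij and mi in one layer, jm in the other) to (M-1) times the
  1-triads centered in i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .build import BinaryMultiplex, WeightedMultiplex

N_LAYERS = 2  # two-layer multiplex throughout

WEIGHT_MODES = ("positive", "absolute", "raw")


def _effective_weights(weights: np.ndarray, mode: str) -> np.ndarray:
    if mode == "positive":
        return np.clip(weights, 0.0, None)
    if mode == "absolute":
        return np.abs(weights)
    if mode == "raw":
        return weights
    raise ValueError(f"unknown weight mode {mode!r}; choose from {WEIGHT_MODES}")


def overlapping_strength(mx: WeightedMultiplex, weight_mode: str = "positive") -> np.ndarray:
    """Per-node overlapping strength s_i = sum_j w_ij^[1] + sum_j w_ij^[2].

    Negative partial correlations are zeroed by default (``positive``),
    keeping s_i >= 0 and matching the binarization convention; ``raw``
    and ``absolute`` handling are available.
    """
    w1 = _effective_weights(mx.layers[0].weights, weight_mode)
    w2 = _effective_weights(mx.layers[1].weights, weight_mode)
    return w1.sum(axis=1) + w2.sum(axis=1)


def layer_degrees(mx: BinaryMultiplex) -> tuple[np.ndarray, np.ndarray]:
    return mx.layers[0].degrees, mx.layers[1].degrees


def overlapping_degree(mx: BinaryMultiplex) -> np.ndarray:
    """o_i = k_i^[1] + k_i^[2]."""
    k1, k2 = layer_degrees(mx)
    return k1 + k2


def _degree_overlap_arrays(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    return (a1 * a2).sum(axis=1)


def _participation_arrays(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    k1 = a1.sum(axis=1)
    k2 = a2.sum(axis=1)
    o = (k1 + k2).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (N_LAYERS / (N_LAYERS - 1)) * (1.0 - (k1 / o) ** 2 - (k2 / o) ** 2)
    p[o == 0] = 0.0
    return np.clip(p, 0.0, 1.0)


def _clustering_arrays(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    # diag(A1 A2 A1) + diag(A2 A1 A2), exploiting symmetry of the layers
    m12 = a1 @ a2
    num = (m12 * a1).sum(axis=1) + (m12.T * a2).sum(axis=1)
    k1 = a1.sum(axis=1)
    k2 = a2.sum(axis=1)
    den = (N_LAYERS - 1) * (k1 * (k1 - 1) + k2 * (k2 - 1))
    c = np.zeros(a1.shape[0], dtype=float)
    nz = den > 0
    c[nz] = num[nz] / den[nz]
    return c


def degree_overlap(mx: BinaryMultiplex) -> np.ndarray:
    """d_i = sum_j a_ij^[1] a_ij^[2] (edges present in both layers)."""
    a1 = mx.layers[0].adjacency.astype(np.int64)
    a2 = mx.layers[1].adjacency.astype(np.int64)
    return _degree_overlap_arrays(a1, a2)


def multiplex_participation(mx: BinaryMultiplex) -> np.ndarray:
    """p_i = (M/(M-1)) [1 - sum_a (k_i^[a]/o_i)^2], with p_i := 0 if o_i = 0.

    Nodes isolated in both layers have an undefined (0/0) evenness; they
    are assigned 0 and can be flagged via ``overlapping_degree == 0``.
    """
    a1 = mx.layers[0].adjacency.astype(np.int64)
    a2 = mx.layers[1].adjacency.astype(np.int64)
    return _participation_arrays(a1, a2)


def multiplex_clustering(mx: BinaryMultiplex) -> np.ndarray:
    """2-triangle clustering c_i, 0 when the node has no 1-triads.

    Numerator: ordered layer pairs (a, b != a) and ordered node pairs
    (j, m), paths i-j (layer a), j-m (layer b), m-i (layer a); the
    cube root in the defining expression is the identity for 0/1 edges.
    Denominator: (M-1) sum_a k_i^[a] (k_i^[a] - 1).
    """
    a1 = mx.layers[0].adjacency.astype(np.float64)
    a2 = mx.layers[1].adjacency.astype(np.float64)
    return _clustering_arrays(a1, a2)


BINARY_MEASURES = {
    "degree_overlap": degree_overlap,
    "multiplex_participation": multiplex_participation,
    "multiplex_clustering": multiplex_clustering,
}

#: Array-level kernels (a1, a2) -> per-node values, used in hot loops.
BINARY_MEASURE_KERNELS = {
    "degree_overlap": _degree_overlap_arrays,
    "multiplex_participation": _participation_arrays,
    "multiplex_clustering": _clustering_arrays,
}


@dataclass
class NodalMetrics:
    """All nodal measures for one multiplex (one density, or weighted)."""

    density_tag: str
    s: np.ndarray | None = None  # overlapping strength (weighted)
    d: np.ndarray | None = None  # degree overlap
    p: np.ndarray | None = None  # multiplex participation
    c: np.ndarray | None = None  # multiplex clustering
    k1: np.ndarray | None = None
    k2: np.ndarray | None = None
    o: np.ndarray | None = None
    region_names: tuple[str, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"s": self.s, "d": self.d, "p": self.p, "c": self.c,
                "k1": self.k1, "k2": self.k2, "o": self.o}
        data = {k: v for k, v in cols.items() if v is not None}
        n = len(next(iter(data.values())))
        idx = list(self.region_names) if self.region_names else list(range(n))
        df = pd.DataFrame(data, index=idx)
        df.index.name = "region"
        df.insert(0, "density", self.density_tag)
        return df


def binary_metrics(mx: BinaryMultiplex) -> NodalMetrics:
    k1, k2 = layer_degrees(mx)
    return NodalMetrics(
        density_tag=f"{mx.density:.2f}",
        d=degree_overlap(mx),
        p=multiplex_participation(mx),
        c=multiplex_clustering(mx),
        k1=k1,
        k2=k2,
        o=k1 + k2,
        region_names=mx.region_names,
    )


def metrics_over_sweep(sweep: list[BinaryMultiplex]) -> dict[float, NodalMetrics]:
    """All binary nodal measures for every density in the sweep."""
    if not sweep:
        raise ValueError("empty density sweep")
    return {float(mx.density): binary_metrics(mx) for mx in sweep}


def sweep_to_frame(metrics: dict[float, NodalMetrics]) -> pd.DataFrame:
    """Tidy long table (density, region, measure, value) for export."""
    frames = []
    for d in sorted(metrics):
        df = metrics[d].to_frame().reset_index()
        df["density"] = d
        frames.append(df.melt(id_vars=["density", "region"],
                              var_name="measure", value_name="value"))
    return pd.concat(frames, ignore_index=True)
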