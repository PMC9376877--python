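"""Permutation-based group comparison of nodal multiplex measures.

The unit of exchangeability is the subject: under the null both groups
share one generative process, so subjects are randomly reallocated to
two pseudo-groups of the original sizes, the whole construction
(residualization -> partial correlation -> binarization per density) is
rerun in each replicate, and the per-region group difference of the
measure is recomputed.  Two-tailed p-values use the add-one convention
p = (#{|null| >= |obs|} + 1) / (n_perm + 1).  Binary-measure p-values
are averaged over the density grid before Benjamini-Hochberg FDR
control across the regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .build import GRID_DENSITIES, _edge_order
from .cohort import RegionalCohort, residualize
from .metrics import BINARY_MEASURES, BINARY_MEASURE_KERNELS, _effective_weights

WEIGHTED_MEASURES = ("overlapping_strength",)
NODAL_MEASURES = WEIGHTED_MEASURES + tuple(BINARY_MEASURES)


def _layer_weights(values, age, sex):
    resid = residualize(values, age, sex)
    corr = np.corrcoef(resid, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return (corr + corr.T) / 2


def _group_measure(gray_vals, amy_vals, age, sex, measure, densities, weight_mode, ranking):
    """Per-region value of a group-level measure.

    Weighted measures return shape (N,); binary measures (n_density, N).
    """
    w_gray = _layer_weights(gray_vals, age, sex)
    w_amy = _layer_weights(amy_vals, age, sex)
    if measure == "overlapping_strength":
        wg = _effective_weights(w_gray, weight_mode)
        wa = _effective_weights(w_amy, weight_mode)
        return wg.sum(axis=1) + wa.sum(axis=1)
    # Binary measures: sort each layer's edges once, then grow the two
    # adjacency matrices incrementally over the (nested) density grid.
    kernel = BINARY_MEASURE_KERNELS[measure]
    n = gray_vals.shape[1]
    n_pairs = n * (n - 1) // 2
    edges = [_edge_order(w, ranking)[:2] for w in (w_gray, w_amy)]
    adj = [np.zeros((n, n)), np.zeros((n, n))]
    out = np.empty((len(densities), n))
    filled = [0, 0]
    order = np.argsort(densities)  # nested thresholds need ascending order
    for k in (int(k) for k in order):
        d = densities[k]
        n_edges = int(round(d * n_pairs))
        for l in range(2):
            ii, jj = edges[l]
            sl = slice(filled[l], n_edges)
            adj[l][ii[sl], jj[sl]] = 1.0
            adj[l][jj[sl], ii[sl]] = 1.0
            filled[l] = n_edges
        out[k] = kernel(adj[0], adj[1])
    return out


@dataclass
class PermutationResult:
    """Observed group difference, permutation null and FDR decisions."""

    measure: str
    group_a: str
    group_b: str
    region_names: tuple[str, ...]
    densities: tuple[float, ...] | None  # None for weighted measures
    observed_diff: np.ndarray  # (N,) or (n_density, N)
    p_raw: np.ndarray  # same shape as observed_diff
    p_mean: np.ndarray  # (N,)
    fdr_mask: np.ndarray  # (N,) bool at q = 0.05
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        obs = self.observed_diff
        obs_region = obs if obs.ndim == 1 else obs.mean(axis=0)
        return pd.DataFrame(
            {
                "measure": self.measure,
                "contrast": f"{self.group_a}_vs_{self.group_b}",
                "region": list(self.region_names),
                "observed_diff": obs_region,
                "p_mean": self.p_mean,
                "significant": self.fdr_mask,
            }
        )


def average_p_across_densities(p_raw: np.ndarray, densities=None) -> np.ndarray:
    """Arithmetic mean of per-density p-values, per region."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim == 1:
        return p.copy()
    if p.shape[0] < 1:
        raise ValueError("need at least one density")
    if not np.all(np.isfinite(p)):
        bad = np.flatnonzero(~np.isfinite(p).all(axis=1))
        labels = [densities[k] for k in bad] if densities is not None else bad.tolist()
        raise ValueError(f"missing p-values at densities: {labels}")
    return p.mean(axis=0)


def fdr_bh(p, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level q."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def permutation_test(
    cohort_a: tuple[RegionalCohort, RegionalCohort],
    cohort_b: tuple[RegionalCohort, RegionalCohort],
    measure: str,
    densities=GRID_DENSITIES,
    n_perm: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
    weight_mode: str = "positive",
    ranking: str = "signed",
    group_a: str | None = None,
    group_b: str | None = None,
) -> PermutationResult:
    """Two-tailed permutation test of a nodal measure between two groups.

    ``cohort_a`` / ``cohort_b`` are (gray-matter, amyloid) cohort pairs
    for the two groups.  Every replicate reallocates subjects (keeping
    each subject's covariates and both modalities together) and reruns
    the full layer construction for both pseudo-groups.
    """
    if measure not in NODAL_MEASURES:
        raise ValueError(f"{measure!r} is not a nodal measure; choose from {NODAL_MEASURES}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    gray_a, amy_a = cohort_a
    gray_b, amy_b = cohort_b
    if gray_a.region_names != gray_b.region_names or gray_a.region_names != amy_a.region_names:
        raise ValueError("cohorts must share the same atlas/region order")
    weighted = measure in WEIGHTED_MEASURES
    dens = None if weighted else tuple(float(d) for d in densities)

    n_a, n_b = gray_a.n_subjects, gray_b.n_subjects
    if min(n_a, n_b) < 5:
        raise ValueError("groups too small for permutation reallocation")
    gray_pool = np.vstack([gray_a.values, gray_b.values])
    amy_pool = np.vstack([amy_a.values, amy_b.values])
    age_pool = np.concatenate([gray_a.age, gray_b.age])
    sex_pool = np.concatenate([gray_a.sex, gray_b.sex])

    def stat(idx_a, idx_b):
        sa = _group_measure(gray_pool[idx_a], amy_pool[idx_a], age_pool[idx_a],
                            sex_pool[idx_a], measure, dens, weight_mode, ranking)
        sb = _group_measure(gray_pool[idx_b], amy_pool[idx_b], age_pool[idx_b],
                            sex_pool[idx_b], measure, dens, weight_mode, ranking)
        return sa - sb

    idx = np.arange(n_a + n_b)
    observed = stat(idx[:n_a], idx[n_a:])
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed, dtype=np.int64)
    abs_obs = np.abs(observed)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        null = stat(perm[:n_a], perm[n_a:])
        exceed += np.abs(null) >= abs_obs - 1e-12
    p_raw = (exceed + 1) / (n_perm + 1)
    p_mean = average_p_across_densities(p_raw, dens)
    return PermutationResult(
        measure=measure,
        group_a=group_a or str(gray_a.group[0]),
        group_b=group_b or str(gray_b.group[0]),
        region_names=tuple(gray_a.region_names),
        densities=dens,
        observed_diff=observed,
        p_raw=p_raw,
        p_mean=p_mean,
        fdr_mask=fdr_bh(p_mean, q),
        n_perm=n_perm,
        seed=seed,
    )
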