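"""End-to-end orchestration: synthesize/load -> layers -> metrics ->
communities -> density sweep -> permutation tests -> FDR.

A :class:`RunConfig` fully determines a run; the same config and seed
reproduce byte-identical numeric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import default_atlas
from .build import (
    GRID_DENSITIES,
    WeightedMultiplex,
    density_sweep,
    partial_corr_layer,
    save_layer,
)
from .cohort import AMYLOID, GRAY_MATTER, GROUPS, load_cohort
from .community import ModularityConfig, louvain_multilayer, sweep_gamma_omega
from .inference import permutation_test
from .metrics import metrics_over_sweep, overlapping_strength, sweep_to_frame
from .synthetic import SyntheticConfig, generate_cohort

#: The study's reported contrasts: every amyloid-positive group against
#: the amyloid-negative controls, plus MCI vs AD.
DEFAULT_CONTRASTS = (
    ("CN_Apos", "CN_Aneg"),
    ("MCI_Apos", "CN_Aneg"),
    ("AD_Apos", "CN_Aneg"),
    ("MCI_Apos", "AD_Apos"),
)

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    gray_table: str | None = None  # load these instead of synthesizing
    amyloid_table: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    d_min: float = 0.02
    d_max: float = 0.30
    d_step: float = 0.01
    weight_mode: str = "positive"
    ranking: str = "signed"
    gamma: float = 1.0
    omega: float = 1.0
    n_restarts: int = 100
    run_gamma_omega_sweep: bool = False
    n_perm: int = 10_000
    fast: bool = False  # 1,000 permutations, 20 restarts
    contrasts: tuple = DEFAULT_CONTRASTS
    measures: tuple = ("overlapping_strength", "degree_overlap",
                       "multiplex_participation", "multiplex_clustering")

    @property
    def effective_n_perm(self) -> int:
        return min(self.n_perm, 1000) if self.fast else self.n_perm

    @property
    def effective_restarts(self) -> int:
        return min(self.n_restarts, 20) if self.fast else self.n_restarts

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["measures"] = list(self.measures)
        d["synthetic"]["amyloid_effect_groups"] = list(self.synthetic.amyloid_effect_groups)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            cov = syn.pop("covariate_effects", None)
            from .synthetic import CovariateEffects

            if cov is not None:
                syn["covariate_effects"] = CovariateEffects(**cov)
            if "amyloid_effect_groups" in syn:
                syn["amyloid_effect_groups"] = tuple(syn["amyloid_effect_groups"])
            if "volume_means" in syn:
                syn["volume_means"] = tuple(syn["volume_means"])
            d["synthetic"] = SyntheticConfig(**syn)
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write provenance-stamped tables.

    Returns the output directory.  Stage order: load/synthesize ->
    preprocess -> per-group layers -> weighted metrics + communities ->
    density sweep + binary metrics -> permutation tests + FDR.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = default_atlas()

    # --- stage 1: cohorts -------------------------------------------------
    if config.gray_table and config.amyloid_table:
        gray = load_cohort(config.gray_table, atlas, GRAY_MATTER)
        amy = load_cohort(config.amyloid_table, atlas, AMYLOID)
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        gray, amy = generate_cohort(syn, atlas)
    gray.to_frame().to_csv(out / "cohort_gray_matter.csv", index=False,
                           float_format=FLOAT_FMT)
    amy.to_frame().to_csv(out / "cohort_amyloid.csv", index=False,
                          float_format=FLOAT_FMT)

    gray_groups = gray.by_group()
    amy_groups = amy.by_group()
    groups = [g for g in GROUPS if g in gray_groups]

    # --- stage 2: layers, weighted metrics, communities -------------------
    strength_rows, community_rows, summary_rows = [], [], []
    multiplexes = {}
    for g in groups:
        lg = partial_corr_layer(gray_groups[g])
        la = partial_corr_layer(amy_groups[g])
        mx = WeightedMultiplex((lg, la), tuple(atlas.region_names))
        multiplexes[g] = mx
        save_layer(lg, out / f"layer_gray_{g}.tsv", atlas.region_names)
        save_layer(la, out / f"layer_amyloid_{g}.tsv", atlas.region_names)

        s = overlapping_strength(mx, config.weight_mode)
        strength_rows.append(pd.DataFrame(
            {"group": g, "region": list(atlas.region_names), "overlapping_strength": s}))

        cfg = ModularityConfig(gamma=config.gamma, omega=config.omega,
                               n_restarts=config.effective_restarts, seed=config.seed)
        part = louvain_multilayer(mx, cfg)
        for layer_idx, layer_name in enumerate((GRAY_MATTER, AMYLOID)):
            community_rows.append(pd.DataFrame(
                {"group": g, "layer": layer_name, "region": list(atlas.region_names),
                 "community": part.labels[layer_idx]}))
        summary_rows.append({"group": g, "n_communities": part.n_communities,
                             "persistence": part.persistence, "Q": part.Q})
        if config.run_gamma_omega_sweep:
            sweep = sweep_gamma_omega(mx, config=cfg)
            sweep.summary().to_csv(out / f"gamma_omega_sweep_{g}.csv", index=False,
                                   float_format=FLOAT_FMT)

    pd.concat(strength_rows, ignore_index=True).to_csv(
        out / "overlapping_strength.csv", index=False, float_format=FLOAT_FMT)
    pd.concat(community_rows, ignore_index=True).to_csv(
        out / "communities.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(summary_rows).to_csv(out / "community_summary.csv", index=False,
                                      float_format=FLOAT_FMT)

    # --- stage 3: density sweep + binary metrics --------------------------
    densities = tuple(round(config.d_min + k * config.d_step, 10)
                      for k in range(int(round((config.d_max - config.d_min) / config.d_step)) + 1))
    binary_frames = []
    for g in groups:
        sweep = density_sweep(multiplexes[g], config.d_min, config.d_max,
                              config.d_step, config.ranking)
        df = sweep_to_frame(metrics_over_sweep(sweep))
        df.insert(0, "group", g)
        binary_frames.append(df)
    pd.concat(binary_frames, ignore_index=True).to_csv(
        out / "binary_metrics.csv", index=False, float_format=FLOAT_FMT)

    # --- stage 4: permutation tests + FDR ---------------------------------
    result_frames = []
    for ga, gb in config.contrasts:
        if ga not in gray_groups or gb not in gray_groups:
            continue
        for measure in config.measures:
            res = permutation_test(
                (gray_groups[ga], amy_groups[ga]),
                (gray_groups[gb], amy_groups[gb]),
                measure,
                densities=densities,
                n_perm=config.effective_n_perm,
                seed=config.seed,
                weight_mode=config.weight_mode,
                ranking=config.ranking,
                group_a=ga,
                group_b=gb,
            )
            result_frames.append(res.to_frame())
    if result_frames:
        pd.concat(result_frames, ignore_index=True).to_csv(
            out / "group_differences.csv", index=False, float_format=FLOAT_FMT)

    # --- provenance -------------------------------------------------------
    prov = {"config": config.to_dict(), "config_hash": _config_hash(config),
            "seed": config.seed, "mxad_version": __version__,
            "numpy_version": np.__version__, "pandas_version": pd.__version__}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    config.to_yaml(out / "run_config.yaml")
    return out
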