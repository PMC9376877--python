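"""Synthetic two-modality cohort generator with planted network structure.

Emulates the statistical structure the pipeline assumes in an
ADNI-like study: four diagnostic groups (135 / 67 / 179 / 132 subjects),
72 regions, per-group block-structured ("planted partition")
region-by-region correlation in each layer, age/sex confounding, TIV
scaling of subcortical volumes, and group-dependent CSF A-beta-42 drawn
so that amyloid stratification reproduces the group sizes exactly.

The generative model is Gaussian: regional values are multivariate
normal draws around modality-specific means with the planted
correlation matrix, plus linear covariate effects.  Nothing about the
real spatial topography of atrophy or amyloid deposition is emulated —
only the covariance structure the network construction consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas import AtlasSpec, default_atlas
from .cohort import (
    ABETA_CUTOFF,
    AMYLOID,
    APOS_GROUPS,
    GRAY_MATTER,
    GROUPS,
    RegionalCohort,
)

#: Published group sizes: CN A-beta-, CN A-beta+, MCI A-beta+, AD A-beta+.
DEFAULT_GROUP_SIZES = {"CN_Aneg": 135, "CN_Apos": 67, "MCI_Apos": 179, "AD_Apos": 132}
#: Module counts per group (the MCI-like group carries three communities).
DEFAULT_MODULES = {"CN_Aneg": 2, "CN_Apos": 2, "MCI_Apos": 3, "AD_Apos": 2}
#: Cross-layer agreement of the planted partitions (expected persistence).
DEFAULT_LAYER_AGREEMENT = {"CN_Aneg": 0.88, "CN_Apos": 0.85, "MCI_Apos": 0.97, "AD_Apos": 0.97}
#: Group medians of CSF A-beta-42 (pg/ml) the CSF draws are centered on.
DEFAULT_CSF_CENTER = {"CN_Aneg": 1587.0, "CN_Apos": 752.9, "MCI_Apos": 686.1, "AD_Apos": 585.2}
#: Group mean amyloid burden (whole-cerebellum SUVR).
DEFAULT_SUVR_CENTER = {"CN_Aneg": 1.05, "CN_Apos": 1.25, "MCI_Apos": 1.30, "AD_Apos": 1.40}


@dataclass
class CovariateEffects:
    """Linear covariate effects added to the generated regional values.

    Slopes are per year of age (centered at 73) and per sex unit, in the
    natural units of each region kind.  TIV acts multiplicatively on
    subcortical volumes (value scaled by TIV / mean TIV).
    """

    age_thickness: float = -0.010  # mm per year
    age_volume: float = -15.0  # mm^3 per year
    age_suvr: float = 0.003  # SUVR per year
    sex_thickness: float = 0.05
    sex_volume: float = 250.0
    sex_suvr: float = 0.0
    tiv_on_volumes: bool = True

    def scaled(self, factor: float) -> "CovariateEffects":
        return CovariateEffects(
            self.age_thickness * factor,
            self.age_volume * factor,
            self.age_suvr * factor,
            self.sex_thickness * factor,
            self.sex_volume * factor,
            self.sex_suvr * factor,
            self.tiv_on_volumes,
        )


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    ``amyloid_effect`` raises every pairwise correlation of the amyloid
    layer in the amyloid-positive groups, planting a group difference in
    amyloid-layer connectivity strength.  ``layer_agreement`` is the
    fraction of regions whose planted community is identical in the two
    layers (the dial for expected persistence).
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_regions: int = 72
    modules_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MODULES))
    within_module_corr: float = 0.45
    between_module_corr: float = 0.10
    layer_agreement: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAYER_AGREEMENT))
    amyloid_effect: float = 0.15
    amyloid_effect_groups: tuple[str, ...] = APOS_GROUPS
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    thickness_mean: float = 2.5  # mm
    thickness_sd: float = 0.15
    volume_means: tuple[float, float, float, float] = (3800.0, 3900.0, 1600.0, 1650.0)
    volume_sd: float = 400.0
    suvr_sd: float = 0.15
    suvr_center: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SUVR_CENTER))
    csf_center: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CSF_CENTER))
    csf_sd: float = 150.0
    seed: int = 0

    def validate(self, atlas: AtlasSpec) -> None:
        if set(self.group_sizes) - set(GROUPS):
            raise ValueError("group_sizes contains unknown group labels")
        for g, n in self.group_sizes.items():
            if n < 4 * 3:  # 4 * (n_covariates + 1) with covariates age, sex
                raise ValueError(f"group {g!r} too small (n={n}) for covariate residualization")
        if not (0 <= self.between_module_corr < self.within_module_corr < 1):
            raise ValueError("need 0 <= between_module_corr < within_module_corr < 1")
        eff = self.within_module_corr + self.amyloid_effect
        if eff >= 1:
            raise ValueError("amyloid_effect pushes within-module correlation to >= 1")
        for g, a in self.layer_agreement.items():
            if not 0 <= a <= 1:
                raise ValueError(f"layer_agreement[{g!r}] must lie in [0, 1]")
        if atlas.n_regions != self.n_regions:
            raise ValueError("atlas size does not match n_regions")


def planted_covariance(module_assignment, within, between, n_regions=None):
    """Block-structured correlation matrix from a community assignment.

    Off-diagonal entries are ``within`` for same-module pairs and
    ``between`` otherwise; the diagonal is 1.  If the construction is not
    positive definite it is projected to the nearest positive-definite
    matrix (eigenvalue clipping) and renormalized to unit diagonal.
    """
    labels = np.asarray(module_assignment)
    if n_regions is None:
        n_regions = len(labels)
    if len(labels) != n_regions:
        raise ValueError("module assignment length must equal n_regions")
    if not (0 <= between <= within < 1):
        raise ValueError("need 0 <= between <= within < 1")
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, within, between).astype(float)
    np.fill_diagonal(cov, 1.0)
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 1e-10:
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 1e-6, None)
        cov = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        np.fill_diagonal(cov, 1.0)
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("planted covariance not repairable to positive definite")
    return cov


def planted_partition(config: SyntheticConfig, group: str, layer: str):
    """Planted community labels for one group, both layers.

    Gray-matter labels split the regions into near-equal contiguous
    blocks; the amyloid labels reassign a ``1 - layer_agreement``
    fraction of regions (chosen reproducibly from the config seed) to a
    different existing module.
    """
    k = config.modules_per_group[group]
    n = config.n_regions
    gray = np.array_split(np.arange(n), k)
    labels = np.empty(n, dtype=int)
    for m, idx in enumerate(gray):
        labels[idx] = m
    if layer == GRAY_MATTER:
        return labels
    if layer != AMYLOID:
        raise ValueError(f"unknown layer {layer!r}")
    n_move = int(round((1.0 - config.layer_agreement[group]) * n))
    rng = np.random.default_rng([config.seed, GROUPS.index(group), 211])
    move = rng.choice(n, size=n_move, replace=False)
    amy = labels.copy()
    amy[move] = (amy[move] + 1 + rng.integers(0, max(k - 1, 1), size=n_move)) % k
    return amy


def _layer_correlations(config: SyntheticConfig, group: str, layer: str):
    within, between = config.within_module_corr, config.between_module_corr
    if layer == AMYLOID and group in config.amyloid_effect_groups:
        within = min(within + config.amyloid_effect, 0.95)
        between = between + config.amyloid_effect
    labels = planted_partition(config, group, layer)
    return planted_covariance(labels, within, between, config.n_regions)


def _truncnorm(rng, lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SyntheticConfig | None = None, atlas: AtlasSpec | None = None):
    """Draw a two-modality cohort (gray matter, amyloid) from the config.

    Returns ``(gray_cohort, amyloid_cohort)``, each a
    :class:`~mxad.cohort.RegionalCohort` over all groups, deterministic
    given ``config.seed``.  Amyloid-positive groups have CSF A-beta-42
    below the 976.6 pg/ml cutoff by construction (truncated normals), so
    stratification by the CSF rule reproduces the configured group sizes
    exactly; the amyloid-negative group may exceed the 1700 pg/ml assay
    ceiling, exercising the clamp.
    """
    config = config or SyntheticConfig()
    atlas = atlas or default_atlas()
    config.validate(atlas)
    rng = np.random.default_rng([config.seed, 1])

    vol_mask = atlas.volume_mask
    vol_idx = np.flatnonzero(vol_mask)
    gm_mean = np.full(config.n_regions, config.thickness_mean)
    gm_mean[vol_idx] = np.asarray(config.volume_means)[: len(vol_idx)]
    gm_scale = np.full(config.n_regions, config.thickness_sd)
    gm_scale[vol_idx] = config.volume_sd

    eff = config.covariate_effects
    gm_age = np.full(config.n_regions, eff.age_thickness)
    gm_age[vol_idx] = eff.age_volume
    gm_sex = np.full(config.n_regions, eff.sex_thickness)
    gm_sex[vol_idx] = eff.sex_volume

    rows_gm, rows_amy = [], []
    ids, ages, sexes, tivs, csfs, groups = [], [], [], [], [], []
    suvr_center = config.suvr_center

    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        age = rng.normal(73.0, 6.0, size=n)
        sex = (rng.random(n) < 0.5).astype(float)
        tiv = rng.normal(1.45e6, 1.2e5, size=n) + 1.0e5 * sex
        if group == "CN_Aneg":
            csf = _truncnorm(rng, ABETA_CUTOFF + 1e-6, 2100.0,
                             config.csf_center[group], config.csf_sd * 2, n)
        else:
            csf = _truncnorm(rng, 250.0, ABETA_CUTOFF - 1e-6,
                             config.csf_center[group], config.csf_sd, n)

        for layer, rows in ((GRAY_MATTER, rows_gm), (AMYLOID, rows_amy)):
            corr = _layer_correlations(config, group, layer)
            L = np.linalg.cholesky(corr)
            z = rng.standard_normal((n, config.n_regions)) @ L.T
            if layer == GRAY_MATTER:
                vals = gm_mean + gm_scale * z
                vals += np.outer(age - 73.0, gm_age) + np.outer(sex, gm_sex)
                if eff.tiv_on_volumes:
                    vals[:, vol_idx] *= (tiv / tiv.mean())[:, None]
            else:
                vals = suvr_center[group] + config.suvr_sd * z
                vals += eff.age_suvr * (age - 73.0)[:, None] + eff.sex_suvr * sex[:, None]
                vals = np.clip(vals, 0.05, None)  # SUVR is positive by definition
            rows.append(vals)

        ids.extend(f"{group}_{i:04d}" for i in range(n))
        ages.append(age)
        sexes.append(sex)
        tivs.append(tiv)
        csfs.append(csf)
        groups.extend([group] * n)

    common = dict(
        subject_ids=np.array(ids),
        region_names=tuple(atlas.region_names),
        age=np.concatenate(ages),
        sex=np.concatenate(sexes),
        csf_abeta42=np.concatenate(csfs),
        group=np.array(groups),
    )
    gray = RegionalCohort(values=np.vstack(rows_gm), modality=GRAY_MATTER,
                          tiv=np.concatenate(tivs), **common)
    amy = RegionalCohort(values=np.vstack(rows_amy), modality=AMYLOID, **common)
    return gray, amy


def null_fixture_config(seed: int, n: int = 160) -> SyntheticConfig:
    """Calibration fixture: one group to be split into two pseudo-groups.

    Both halves share a single generative process, so any downstream
    two-group test must reject at its nominal rate.
    """
    return SyntheticConfig(
        group_sizes={"CN_Aneg": n},
        modules_per_group={"CN_Aneg": 2},
        layer_agreement={"CN_Aneg": 1.0},
        seed=seed,
    )


def power_fixture_config(seed: int, effect: float = 0.3) -> SyntheticConfig:
    """Connectivity-recovery fixture: a planted amyloid-layer correlation
    increase of ``effect`` in the CN amyloid-positive group.

    The two groups share the planted module layout and the mean amyloid
    burden, so the only systematic group difference is the amyloid-layer
    connectivity increase itself: the contrast isolates the planted
    parameter from mean-shift confounds (see the methods note).
    """
    return SyntheticConfig(
        group_sizes={"CN_Aneg": 135, "CN_Apos": 67},
        modules_per_group={"CN_Aneg": 2, "CN_Apos": 2},
        layer_agreement={"CN_Aneg": 1.0, "CN_Apos": 1.0},
        suvr_center={"CN_Aneg": 1.2, "CN_Apos": 1.2},
        amyloid_effect=effect,
        seed=seed,
    )


def split_cohort(gray: RegionalCohort, amy: RegionalCohort, n_a: int, rng):
    """Randomly split one cohort into two pseudo-groups of sizes n_a / rest.

    Used for null calibration: both halves come from the same generative
    process, so any group test between them should reject at its nominal
    rate.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = gray.n_subjects
    perm = rng.permutation(n)
    a, b = perm[:n_a], perm[n_a:]
    return (gray.subset(a), amy.subset(a)), (gray.subset(b), amy.subset(b))
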