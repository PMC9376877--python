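"""Region atlas for the 72-node gray-matter / amyloid multiplex.

The node set is the 68 cortical Desikan-Killiany regions (34 per
hemisphere, mean cortical thickness) plus the bilateral hippocampus and
amygdala from the subcortical segmentation (volumes).  The same ordered
region list defines the nodes of both network layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CORTICAL_THICKNESS = "cortical_thickness"
SUBCORTICAL_VOLUME = "subcortical_volume"

#: Desikan-Killiany cortical parcels, one hemisphere (34 labels).
DESIKAN_PARCELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Subcortical (aseg) structures included alongside the cortical parcels.
SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "Left-Hippocampus",
    "Right-Hippocampus",
    "Left-Amygdala",
    "Right-Amygdala",
)


@dataclass(frozen=True)
class AtlasSpec:
    """Ordered region list shared by both multiplex layers.

    Attributes
    ----------
    region_names : tuple of str
        Ordered region labels (network node order).
    hemisphere : tuple of str
        ``"L"`` or ``"R"`` per region.
    region_kind : tuple of str
        ``"cortical_thickness"`` or ``"subcortical_volume"`` per region.
    """

    region_names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    region_kind: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.region_names)
        if len(self.hemisphere) != n or len(self.region_kind) != n:
            raise ValueError("atlas fields must have equal length")
        if len(set(self.region_names)) != n:
            raise ValueError("duplicate region names in atlas")
        bad = set(self.region_kind) - {CORTICAL_THICKNESS, SUBCORTICAL_VOLUME}
        if bad:
            raise ValueError(f"unknown region kind(s): {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def volume_mask(self):
        import numpy as np

        return np.array([k == SUBCORTICAL_VOLUME for k in self.region_kind])

    def index_of(self, name: str) -> int:
        return self.region_names.index(name)


def default_atlas() -> AtlasSpec:
    """The 72-region atlas: 68 Desikan cortical + 4 subcortical labels."""
    names: list[str] = []
    hemi: list[str] = []
    kind: list[str] = []
    for prefix, h in (("lh_", "L"), ("rh_", "R")):
        for parcel in DESIKAN_PARCELS:
            names.append(prefix + parcel)
            hemi.append(h)
            kind.append(CORTICAL_THICKNESS)
    for region in SUBCORTICAL_REGIONS:
        names.append(region)
        hemi.append("L" if region.startswith("Left") else "R")
        kind.append(SUBCORTICAL_VOLUME)
    return AtlasSpec(tuple(names), tuple(hemi), tuple(kind))
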