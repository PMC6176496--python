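"""The 148-ROI Destrieux parcellation and its grouping into 14 cortical areas.

The Destrieux scheme has 74 gyral/sulcal regions per hemisphere. For the
long/short-distance analysis each ROI belongs to one of 14 coarse areas —
ventral prefrontal (VPF), dorsal prefrontal (DPF), central (C), temporal (T),
parietal (P), occipital (O) and cingulate (Cing), per hemisphere. No
authoritative region-to-area table exists for this grouping, so the default
assignment below is a best-effort keyword mapping over the standard
aparc.a2009s region names; it ships as an editable CSV
(``data/destrieux_14area.csv``) that users can replace via ``load_atlas``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .config import ConfigError

#: the 14 coarse cortical areas in the order used by the result tables
AREA_CODES = ["LVPF", "LDPF", "LC", "LT", "LP", "LO", "LCing",
              "RVPF", "RDPF", "RC", "RT", "RP", "RO", "RCing"]

# 74 Destrieux (aparc.a2009s) region names per hemisphere with their coarse
# area: VPF ventral prefrontal, DPF dorsal prefrontal, C central, T temporal
# (incl. insula), P parietal, O occipital, Cing cingulate.
_DESTRIEUX_74 = [
    ("G_and_S_frontomargin", "VPF"),
    ("G_and_S_occipital_inf", "O"),
    ("G_and_S_paracentral", "C"),
    ("G_and_S_subcentral", "C"),
    ("G_and_S_transv_frontopol", "VPF"),
    ("G_and_S_cingul-Ant", "Cing"),
    ("G_and_S_cingul-Mid-Ant", "Cing"),
    ("G_and_S_cingul-Mid-Post", "Cing"),
    ("G_cingul-Post-dorsal", "Cing"),
    ("G_cingul-Post-ventral", "Cing"),
    ("G_cuneus", "O"),
    ("G_front_inf-Opercular", "VPF"),
    ("G_front_inf-Orbital", "VPF"),
    ("G_front_inf-Triangul", "VPF"),
    ("G_front_middle", "DPF"),
    ("G_front_sup", "DPF"),
    ("G_Ins_lg_and_S_cent_ins", "T"),
    ("G_insular_short", "T"),
    ("G_occipital_middle", "O"),
    ("G_occipital_sup", "O"),
    ("G_oc-temp_lat-fusifor", "T"),
    ("G_oc-temp_med-Lingual", "O"),
    ("G_oc-temp_med-Parahip", "T"),
    ("G_orbital", "VPF"),
    ("G_pariet_inf-Angular", "P"),
    ("G_pariet_inf-Supramar", "P"),
    ("G_parietal_sup", "P"),
    ("G_postcentral", "C"),
    ("G_precentral", "C"),
    ("G_precuneus", "P"),
    ("G_rectus", "VPF"),
    ("G_subcallosal", "VPF"),
    ("G_temp_sup-G_T_transv", "T"),
    ("G_temp_sup-Lateral", "T"),
    ("G_temp_sup-Plan_polar", "T"),
    ("G_temp_sup-Plan_tempo", "T"),
    ("G_temporal_inf", "T"),
    ("G_temporal_middle", "T"),
    ("Lat_Fis-ant-Horizont", "VPF"),
    ("Lat_Fis-ant-Vertical", "VPF"),
    ("Lat_Fis-post", "T"),
    ("Pole_occipital", "O"),
    ("Pole_temporal", "T"),
    ("S_calcarine", "O"),
    ("S_central", "C"),
    ("S_cingul-Marginalis", "Cing"),
    ("S_circular_insula_ant", "T"),
    ("S_circular_insula_inf", "T"),
    ("S_circular_insula_sup", "T"),
    ("S_collat_transv_ant", "T"),
    ("S_collat_transv_post", "O"),
    ("S_front_inf", "DPF"),
    ("S_front_middle", "DPF"),
    ("S_front_sup", "DPF"),
    ("S_interm_prim-Jensen", "P"),
    ("S_intrapariet_and_P_trans", "P"),
    ("S_oc_middle_and_Lunatus", "O"),
    ("S_oc_sup_and_transversal", "O"),
    ("S_occipital_ant", "O"),
    ("S_oc-temp_lat", "T"),
    ("S_oc-temp_med_and_Lingual", "O"),
    ("S_orbital_lateral", "VPF"),
    ("S_orbital_med-olfact", "VPF"),
    ("S_orbital-H_Shaped", "VPF"),
    ("S_parieto_occipital", "P"),
    ("S_pericallosal", "Cing"),
    ("S_postcentral", "C"),
    ("S_precentral-inf-part", "C"),
    ("S_precentral-sup-part", "C"),
    ("S_suborbital", "VPF"),
    ("S_subparietal", "P"),
    ("S_temporal_inf", "T"),
    ("S_temporal_sup", "T"),
    ("S_temporal_transverse", "T"),
]


@dataclass
class AreaPartition:
    """Maps each of N ROIs to one of the 14 coarse areas."""

    area_of: np.ndarray  # ROI index (0-based) -> area index (0..13)
    area_names: list[str]

    def __post_init__(self) -> None:
        self.area_of = np.asarray(self.area_of, dtype=int)
        n_areas = len(self.area_names)
        if self.area_of.min(initial=0) < 0 or \
                self.area_of.max(initial=0) >= n_areas:
            raise ConfigError("area indices out of range")
        counts = np.bincount(self.area_of, minlength=n_areas)
        if np.any(counts == 0):
            empty = [self.area_names[i] for i in np.flatnonzero(counts == 0)]
            raise ConfigError(f"empty areas in partition: {empty}")

    @property
    def n_rois(self) -> int:
        return len(self.area_of)

    @property
    def n_areas(self) -> int:
        return len(self.area_names)


def destrieux_table() -> pd.DataFrame:
    """The default 148-row atlas table: roi_id, roi_name, area."""
    rows = []
    rid = 1
    for hemi in ("L", "R"):
        for name, area in _DESTRIEUX_74:
            rows.append({"roi_id": rid, "roi_name": f"{hemi}_{name}",
                         "area": f"{hemi}{area}"})
            rid += 1
    return pd.DataFrame(rows)


def partition_from_table(table: pd.DataFrame,
                         n_rois: int | None = None) -> AreaPartition:
    """Validate an atlas table and build the ROI-to-area partition.

    The table must cover ROI ids 1..N exactly once each, with every area
    named in ``AREA_CODES`` and none empty.
    """
    required = {"roi_id", "roi_name", "area"}
    if not required.issubset(table.columns):
        raise ConfigError(f"atlas table needs columns {sorted(required)}")
    n = n_rois or len(table)
    ids = np.sort(table["roi_id"].to_numpy())
    expected = np.arange(1, n + 1)
    if len(ids) != n or not np.array_equal(ids, expected):
        missing = sorted(int(i) for i in set(expected) - set(ids))
        raise ConfigError(f"atlas must list ROI ids 1..{n} exactly once; "
                          f"missing {missing[:10]}")
    bad = set(table["area"]) - set(AREA_CODES)
    if bad:
        raise ConfigError(f"unknown area codes in atlas: {sorted(bad)}")
    ordered = table.sort_values("roi_id")
    area_of = np.array([AREA_CODES.index(a) for a in ordered["area"]])
    return AreaPartition(area_of, list(AREA_CODES))


def default_partition() -> AreaPartition:
    return partition_from_table(destrieux_table())


def load_atlas(path) -> tuple[pd.DataFrame, AreaPartition]:
    """Read an atlas CSV (roi_id, roi_name, area) and validate it."""
    table = pd.read_csv(path)
    return table, partition_from_table(table)


def default_atlas_path():
    """Path of the shipped editable atlas CSV."""
    return resources.files("mmnconn").joinpath("data/destrieux_14area.csv")


def balanced_partition(n_rois: int, n_areas: int = 14) -> AreaPartition:
    """Contiguous near-equal grouping of N ROIs into the 14 areas.

    Used for reduced-size simulations where the anatomical table does not
    apply; requires n_rois >= n_areas.
    """
    if n_rois < n_areas:
        raise ConfigError("need at least one ROI per area")
    area_of = (np.arange(n_rois) * n_areas) // n_rois
    return AreaPartition(area_of, list(AREA_CODES[:n_areas]))
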