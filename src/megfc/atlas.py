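"""Cortical parcel atlas handling.

The analysis grid is the 74-parcel Destrieux gyral/sulcal parcellation
(one label set over the whole cortical surface, matching the emulated
study's merged grid).  Atlases round-trip through a two-column TSV
(parcel index, label).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DESTRIEUX_74",
    "DEFAULT_DIFFERENTIAL_EDGE_LABELS",
    "default_atlas",
    "load_atlas",
    "save_atlas",
    "edges_from_labels",
]

# Standard Destrieux (aparc.a2009s) cortical labels.
DESTRIEUX_74 = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)


# Default planted group-difference edges for the synthetic cohort: the
# strongest CPS-vs-SPS discriminative connections reported for the emulated
# clinical cohort (frontal-parietal / occipital-cingulate pairs).
DEFAULT_DIFFERENTIAL_EDGE_LABELS = (
    ("G_pariet_inf-Angular", "G_front_middle"),
    ("S_parieto_occipital", "G_cuneus"),
    ("S_interm_prim-Jensen", "G_front_middle"),
    ("S_intrapariet_and_P_trans", "G_cingul-Post-ventral"),
    ("G_cingul-Post-ventral", "G_and_S_cingul-Mid-Post"),
)


def edges_from_labels(label_pairs, atlas: pd.DataFrame | None = None
                      ) -> tuple[tuple[int, int], ...]:
    """Resolve (label, label) pairs to sorted parcel-index edges."""
    if atlas is None:
        atlas = default_atlas()
    lookup = {lab: int(i) for i, lab in zip(atlas["index"], atlas["label"])}
    return tuple(tuple(sorted((lookup[a], lookup[b])))
                 for a, b in label_pairs)


def default_atlas(n_parcels: int = 74) -> pd.DataFrame:
    """Atlas table (index, label) for the analysis grid.

    For 74 parcels the Destrieux labels are used; other sizes get
    numbered placeholder labels (reduced synthetic grids).
    """
    if n_parcels == len(DESTRIEUX_74):
        labels = list(DESTRIEUX_74)
    else:
        labels = [f"parcel_{i:03d}" for i in range(n_parcels)]
    return pd.DataFrame({"index": range(n_parcels), "label": labels})


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    if df["label"].duplicated().any():
        raise ValueError("atlas labels must be unique")
    if not (df["index"].to_numpy() == range(len(df))).all():
        raise ValueError("atlas indices must be 0..n-1 in order")
    return df


def load_atlas(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path, sep="\t", dtype={"index": int,
                                                        "label": str}))


def save_atlas(df: pd.DataFrame, path) -> None:
    _validate(df).to_csv(path, sep="\t", index=False)
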