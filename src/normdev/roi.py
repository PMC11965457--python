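"""ROI dictionaries for the three morphometry modalities.

Defaults follow a Destrieux-style gyral/sulcal parcellation: 74 cortical
labels per hemisphere (148 thickness ROIs and 148 area ROIs) plus 31
subcortical volume structures, 327 regions in total.  The dictionary is
fully configurable; any subjects-by-ROIs table whose columns are listed
in a dictionary can be analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MODALITIES = ("thickness", "area", "volume")

# Destrieux gyral/sulcal labels, one hemisphere (74 labels).
_DESTRIEUX = [
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
]

# 31 subcortical structures: 14 bilateral + 3 midline.
_SUBCORTICAL_BILATERAL = [
    "Lateral-Ventricle",
    "Inf-Lat-Vent",
    "Cerebellum-White-Matter",
    "Cerebellum-Cortex",
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
    "choroid-plexus",
    "vessel",
]
_SUBCORTICAL_MIDLINE = ["3rd-Ventricle", "4th-Ventricle", "Brain-Stem"]

_LOBE_PREFIXES = {
    "front": "frontal",
    "precentral": "frontal",
    "orbital": "frontal",
    "rectus": "frontal",
    "suborbital": "frontal",
    "subcallosal": "frontal",
    "cingul": "limbic",
    "pericallosal": "limbic",
    "insul": "insula",
    "temp": "temporal",
    "occipital": "occipital",
    "oc-temp": "occipito-temporal",
    "cuneus": "occipital",
    "calcarine": "occipital",
    "lingual": "occipital",
    "pariet": "parietal",
    "postcentral": "parietal",
    "precuneus": "parietal",
    "central": "central",
    "paracentral": "central",
}


def _lobe_tag(name: str) -> str:
    low = name.lower()
    for key, tag in _LOBE_PREFIXES.items():
        if key in low:
            return tag
    return "other"


@dataclass
class ROIDictionary:
    """Catalog of region names per modality with hemisphere/lobe tags.

    table columns: name, hemisphere ('left'/'right'/'none'), modality,
    lobe.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"name", "hemisphere", "modality", "lobe"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ROI dictionary missing columns: {sorted(missing)}")
        for modality in self.table["modality"].unique():
            names = self.names(modality)
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate ROI names for modality {modality!r}")

    def names(self, modality: str) -> list[str]:
        sub = self.table[self.table["modality"] == modality]
        return sub["name"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, modality: str, n: int | None = None) -> "ROIDictionary":
        """Restrict to one modality, optionally to its first n regions."""
        sub = self.table[self.table["modality"] == modality]
        if n is not None:
            sub = sub.iloc[:n]
        return ROIDictionary(sub.reset_index(drop=True))


def default_roi_dictionary(
    n_cortical: int | None = None, n_subcortical: int | None = None
) -> ROIDictionary:
    """Destrieux-style default: 148 thickness + 148 area + 31 volume ROIs.

    ``n_cortical`` / ``n_subcortical`` truncate each catalog, which is how
    the test-suite and demo configurations run reduced-size analyses with
    the same region names.
    """
    rows = []
    cortical = [("lh", "left"), ("rh", "right")]
    for modality in ("thickness", "area"):
        labels = [
            (f"{hemi}_{label}", side) for hemi, side in cortical for label in _DESTRIEUX
        ]
        if n_cortical is not None:
            labels = labels[:n_cortical]
        for name, side in labels:
            rows.append((name, side, modality, _lobe_tag(name)))
    sub = [(f"Left-{s}", "left") for s in _SUBCORTICAL_BILATERAL]
    sub += [(f"Right-{s}", "right") for s in _SUBCORTICAL_BILATERAL]
    sub += [(s, "none") for s in _SUBCORTICAL_MIDLINE]
    if n_subcortical is not None:
        sub = sub[:n_subcortical]
    for name, side in sub:
        rows.append((name, side, "volume", "subcortical"))
    table = pd.DataFrame(rows, columns=["name", "hemisphere", "modality", "lobe"])
    return ROIDictionary(table)
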