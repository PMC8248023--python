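"""AAL-90 parcellation labels and hemisphere conventions.

The 90-region Automated Anatomical Labeling (AAL) atlas is the standard
cortical/subcortical parcellation for streamline-count connectomes at this
resolution.  Regions are listed in the canonical atlas order, in which
homotopic left/right pairs are interleaved: 1-based odd indices are left-
hemisphere regions, even indices their right-hemisphere homologues.
"""

from __future__ import annotations

import pandas as pd

#: Canonical AAL-90 region names, 1-based index = position + 1.
AAL90_REGIONS: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
)


def hemisphere_of(index: int) -> str:
    """Hemisphere of a 1-based AAL index: odd = left, even = right."""
    if index < 1:
        raise ValueError(f"AAL indices are 1-based; got {index}")
    return "L" if index % 2 == 1 else "R"


def node_table(n_nodes: int = 90) -> pd.DataFrame:
    """Node-label table (1-based index, region name, hemisphere).

    For ``n_nodes`` = 90 the AAL-90 names are used; for other sizes generic
    mirrored ``Region_<k>_{L,R}`` names are generated so the odd/even
    hemisphere convention still holds.
    """
    idx = range(1, n_nodes + 1)
    if n_nodes == 90:
        names = list(AAL90_REGIONS)
    else:
        names = [f"Region_{(i + 1) // 2}_{hemisphere_of(i)}" for i in idx]
    return pd.DataFrame(
        {"index": list(idx), "name": names, "hemisphere": [hemisphere_of(i) for i in idx]}
    )


#: Demo template: a 16-connection fronto-subcortical sub-network with seven
#: strengthening and nine weakening connections, the kind of mixed-sign
#: longitudinal component this pipeline is designed to detect.  Each entry is
#: (area_1, area_2, connectivity difference timepoint2 - timepoint1) with
#: 1-based AAL indices.  The edge set is connected, so a planted effect on it
#: forms a single NBS component.
DEMO_COMPONENT: tuple[tuple[int, int, float], ...] = (
    # increases
    (77, 74, 0.008),
    (78, 73, 0.009),
    (76, 73, 0.009),
    (77, 33, 0.013),
    (73, 31, 0.013),
    (78, 77, 0.019),
    (34, 33, 0.044),
    # decreases
    (78, 72, -0.088),
    (34, 20, -0.040),
    (72, 4, -0.028),
    (34, 32, -0.026),
    (72, 24, -0.022),
    (71, 3, -0.016),
    (73, 7, -0.014),
    (24, 3, -0.011),
    (77, 7, -0.010),
)
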