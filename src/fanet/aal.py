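"""Automated Anatomical Labeling (AAL) 90-region parcellation lookup.

The 90-node cortical/subcortical parcellation (45 regions per hemisphere,
cerebellum excluded) is the standard node definition for whole-brain
structural connectomes.  Region indices are 1-based in the AAL convention
and at every user-facing boundary of this package; matrix rows/columns are
0-based internally (AAL index ``i`` maps to row ``i - 1``).
"""

from __future__ import annotations

# Standard AAL-90 ordering: odd indices left hemisphere, even indices right.
AAL90_LABELS: tuple[str, ...] = (
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

N_AAL90 = len(AAL90_LABELS)

_NAME_TO_INDEX = {name: i + 1 for i, name in enumerate(AAL90_LABELS)}

# Nodes where ASD-related nodal-efficiency elevation is injected by the
# synthetic-cohort generator (1-based AAL indices): left precuneus, left
# thalamus, and bilateral superior parietal cortex.
DEFAULT_TARGET_NODES: tuple[int, ...] = (
    _NAME_TO_INDEX["Precuneus_L"],
    _NAME_TO_INDEX["Thalamus_L"],
    _NAME_TO_INDEX["Parietal_Sup_L"],
    _NAME_TO_INDEX["Parietal_Sup_R"],
)


def region_index(name: str) -> int:
    """Return the 1-based AAL index of a region name."""
    try:
        return _NAME_TO_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown AAL region name: {name!r}") from None


def region_name(index: int) -> str:
    """Return the region name for a 1-based AAL index."""
    if not 1 <= index <= N_AAL90:
        raise IndexError(f"AAL index out of range 1..{N_AAL90}: {index}")
    return AAL90_LABELS[index - 1]
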