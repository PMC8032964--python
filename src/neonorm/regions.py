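"""Region registry for the neonatal volumetric pipeline.

Thirteen regional volumes are modelled with their own normative curve:
twelve segmented structures plus total tissue volume (TTV), which is the
sum of cortical grey matter, white matter, cerebellum, brainstem, total
deep grey matter and hippocampus+amygdala.  Hippocampus+amygdala and the
deep-grey total are carried in the data only to build TTV; they do not
receive their own normative model.
"""

from __future__ import annotations

#: Segmented structures generated for every subject (column ``vol_<name>``).
SEGMENTED_REGIONS: tuple[str, ...] = (
    "cortical_gm",
    "white_matter",
    "extracerebral_csf",
    "ventricles",
    "cerebellum",
    "brainstem",
    "thalamus_l",
    "thalamus_r",
    "lentiform_l",
    "lentiform_r",
    "caudate_l",
    "caudate_r",
    "hippocampus_amygdala",
    "deep_gm_total",
)

#: Regions that get their own normative model (order mirrors the report tables).
MODELLED_REGIONS: tuple[str, ...] = (
    "cortical_gm",
    "white_matter",
    "extracerebral_csf",
    "ventricles",
    "cerebellum",
    "brainstem",
    "thalamus_l",
    "thalamus_r",
    "lentiform_l",
    "lentiform_r",
    "caudate_l",
    "caudate_r",
    "ttv",
)

#: Constituents summed into total tissue volume (CSF spaces excluded).
TTV_COMPONENTS: tuple[str, ...] = (
    "cortical_gm",
    "white_matter",
    "cerebellum",
    "brainstem",
    "deep_gm_total",
    "hippocampus_amygdala",
)

#: Bilateral deep grey structures (thalami, lentiform and caudate nuclei).
DEEP_GREY_REGIONS: tuple[str, ...] = (
    "thalamus_l",
    "thalamus_r",
    "lentiform_l",
    "lentiform_r",
    "caudate_l",
    "caudate_r",
)

#: CSF-space volumes with right-skewed population distributions; normative
#: models log-transform these by default.
SKEWED_REGIONS: tuple[str, ...] = ("extracerebral_csf", "ventricles")

#: Volumes excluded when an arterial ischaemic stroke distorts the cortical
#: segmentation; subcortical and infratentorial volumes remain usable.
STROKE_MASKED_REGIONS: tuple[str, ...] = ("cortical_gm", "white_matter", "ttv")


def volume_column(region: str) -> str:
    """Cohort-table column name holding a region's volume in cm^3."""
    return f"vol_{region}"


def check_region(region: str, valid: tuple[str, ...] = MODELLED_REGIONS) -> str:
    if region not in valid:
        raise KeyError(
            f"unknown region {region!r}; valid regions: {', '.join(valid)}"
        )
    return region
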