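"""Registry of Destrieux-atlas sulcus labels supported by the estimator.

The eight supported sulci are those for which boundary edge-loop extraction
succeeds at an acceptable rate on FreeSurfer parcellations: central,
post-central, superior frontal, inferior frontal, parieto-occipital,
occipito-temporal, middle occipital and lunate, and the marginal part of the
cingulate.  The superior/inferior temporal and intraparietal sulci are known
to be parcellated as discontinuous regions too often (failure rate above 10%)
and are available only as *experimental* labels.

Label strings follow FreeSurfer v6.0 naming of the Destrieux (a2009s) atlas.
"""

#: The eight supported Destrieux sulcus labels (per hemisphere -> 16 measures).
SUPPORTED_SULCI: tuple[str, ...] = (
    "S_central",
    "S_postcentral",
    "S_front_sup",
    "S_front_inf",
    "S_parieto_occipital",
    "S_oc-temp_med&Lingual",
    "S_oc_middle&Lunatus",
    "S_cingul-Marginalis",
)

#: Labels measurable only with an explicit experimental opt-in.
EXPERIMENTAL_SULCI: tuple[str, ...] = (
    "S_temporal_sup",
    "S_temporal_inf",
    "S_intrapariet&P_trans",
)

#: Human-readable names, for reports.
SULCUS_DESCRIPTIONS: dict[str, str] = {
    "S_central": "central",
    "S_postcentral": "post-central",
    "S_front_sup": "superior frontal",
    "S_front_inf": "inferior frontal",
    "S_parieto_occipital": "parieto-occipital",
    "S_oc-temp_med&Lingual": "occipito-temporal",
    "S_oc_middle&Lunatus": "middle occipital and lunate",
    "S_cingul-Marginalis": "marginal part of the cingulate",
    "S_temporal_sup": "superior temporal (experimental)",
    "S_temporal_inf": "inferior temporal (experimental)",
    "S_intrapariet&P_trans": "intraparietal (experimental)",
}

HEMISPHERES: tuple[str, ...] = ("lh", "rh")
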