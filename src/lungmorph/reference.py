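"""Published group-level reference morphometry for the three study groups.

These are the per-case mean (standard deviation) morphometric statistics
reported for lungs of divers dead of arterial gas embolism following
pulmonary barotrauma (``pbt``), of saltwater drowning victims (``drowning``,
positive controls) and of non-diver intracerebral-bleed deaths (``control``,
negative controls).  They parameterize the cohort simulators and serve as
benchmarks for diagnostic discrimination.

Units: CAS counts are air spaces per case (summed over 24 fields) or per
field; AAS is the per-field mean total air-space area in µm²; the AAS/CAS
ratio is µm² per air space (per-field ratio averaged over fields); PAS is the
percentage of field area occupied by air spaces; MaxDAS/MinDAS are mean
maximum/minimum Feret diameters in µm.
"""

from __future__ import annotations

GROUPS = ("pbt", "drowning", "control")

#: Morphometric parameter -> group -> (mean, sd).
GROUP_REFERENCE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "total_cas": {
        "pbt": (1503.0, 606.0),
        "drowning": (1973.0, 665.0),
        "control": (2312.0, 1077.0),
    },
    "mean_cas_per_field": {
        "pbt": (62.60, 25.26),
        "drowning": (85.80, 33.04),
        "control": (96.32, 44.89),
    },
    "mean_aas_um2": {
        "pbt": (856_950.0, 102_849.0),
        "drowning": (494_977.0, 106_953.0),
        "control": (547_856.0, 201_029.0),
    },
    "mean_ratio_aas_cas_um2": {
        "pbt": (22_968.0, 8_883.0),
        "drowning": (7_807.0, 3_536.0),
        "control": (8_708.0, 5_094.0),
    },
    "mean_pas_percent": {
        "pbt": (65.47, 7.86),
        "drowning": (37.82, 8.17),
        "control": (41.86, 15.36),
    },
    "mean_max_das_um": {
        "pbt": (144.54, 32.27),
        "drowning": (92.51, 17.40),
        "control": (95.90, 35.91),
    },
    "mean_min_das_um": {
        "pbt": (76.94, 21.35),
        "drowning": (47.33, 12.67),
        "control": (53.12, 18.84),
    },
}

#: Reported ROC area under the curve for barotrauma vs pooled controls.
REFERENCE_AUC: dict[str, float] = {
    "mean_aas_um2": 0.944,
    "mean_ratio_aas_cas_um2": 0.903,
    "mean_pas_percent": 0.944,
    "mean_max_das_um": 0.917,
    "mean_min_das_um": 0.806,
}

#: The five parameters entering the diagnostic (ROC) layer, in report order.
DIAGNOSTIC_PARAMETERS = (
    "mean_aas_um2",
    "mean_ratio_aas_cas_um2",
    "mean_pas_percent",
    "mean_max_das_um",
    "mean_min_das_um",
)
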