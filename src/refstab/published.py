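"""Published per-gene statistics for the 13-candidate soybean reference panel.

A published evaluation of 13 candidate soybean reference genes under
dehydration, salt, cold and ABA treatment reports, for every condition
stratum, each gene's delta-CT stability statistic (the mean over partner
genes of the population SD of pairwise delta-CT, in cycles), together with
per-amplicon amplification efficiencies and a fold-change validation of
four stress-inducible GmNAC targets under good and bad references. Those
printed values are inputs here: they let the recommendation and
detection-consistency stages be exercised and checked without the raw
per-well data.

``DELTACT_BY_STRESS[stress][column]`` maps gene -> statistic for the
per-stress strata (columns ``roots``, ``shoots``, ``both``);
``DELTACT_ALL_STRESS`` holds the all-stresses-combined strata.
``RECOMMENDED_PAIRS`` is the published pair per cell, most stable first.
"""

from __future__ import annotations

GENES = (
    "60s", "ABC", "Act27", "Act11", "CDPK", "CYP2", "ELF1a",
    "ELF1b", "Fbox", "IDE", "SUBI2", "TUBa", "TUBb",
)

#: Per-amplicon amplification efficiencies (fold per cycle).
EFFICIENCIES = {
    "60s": 1.910,
    "ABC": 1.866,
    "Act11": 1.873,
    "Act27": 1.858,
    "CDPK": 1.885,
    "CYP2": 1.855,
    "ELF1a": 1.824,
    "ELF1b": 1.870,
    "Fbox": 1.883,
    "IDE": 1.884,
    "SUBI2": 1.862,
    "TUBa": 1.861,
    "TUBb": 1.844,
}

#: Mean CT per gene in the all-stress pool (roots, shoots).
MEAN_CT_ALL_STRESS = {
    "60s": (21.31, 21.97),
    "ABC": (23.64, 24.38),
    "Act27": (21.64, 22.03),
    "Act11": (19.11, 19.70),
    "CDPK": (25.79, 26.35),
    "CYP2": (17.63, 17.68),
    "ELF1a": (18.41, 18.87),
    "ELF1b": (20.67, 21.86),
    "Fbox": (21.09, 21.55),
    "IDE": (21.66, 22.41),
    "SUBI2": (25.30, 26.65),
    "TUBa": (20.12, 20.34),
    "TUBb": (20.60, 21.16),
}

#: All-stress delta-CT stability statistic (cycles), by stratum.
DELTACT_ALL_STRESS = {
    "roots": {
        "60s": 0.4274, "ABC": 0.4580, "Act27": 0.5325, "Act11": 0.5772,
        "CDPK": 0.7810, "CYP2": 0.5148, "ELF1a": 0.5210, "ELF1b": 0.4204,
        "Fbox": 0.4908, "IDE": 0.5284, "SUBI2": 0.9455, "TUBa": 0.8019,
        "TUBb": 0.5258,
    },
    "shoots": {
        "60s": 0.5112, "ABC": 0.5851, "Act27": 0.6736, "Act11": 0.5761,
        "CDPK": 0.8356, "CYP2": 0.5897, "ELF1a": 0.5905, "ELF1b": 0.5462,
        "Fbox": 0.5115, "IDE": 0.5518, "SUBI2": 1.1124, "TUBa": 1.1125,
        "TUBb": 0.7495,
    },
    "both": {
        "60s": 0.4492, "ABC": 0.5238, "Act27": 0.5837, "Act11": 0.5682,
        "CDPK": 0.8015, "CYP2": 0.5987, "ELF1a": 0.5541, "ELF1b": 0.5233,
        "Fbox": 0.4843, "IDE": 0.5333, "SUBI2": 1.0802, "TUBa": 0.9594,
        "TUBb": 0.6293,
    },
}

#: Per-stress delta-CT stability statistic (cycles), by stratum.
DELTACT_BY_STRESS = {
    "dehydration": {
        "roots": {
            "60s": 0.2902, "ABC": 0.2145, "Act27": 0.2179, "Act11": 0.2159,
            "CDPK": 0.2437, "CYP2": 0.2807, "ELF1a": 0.2362, "ELF1b": 0.2378,
            "Fbox": 0.2026, "IDE": 0.2439, "SUBI2": 0.5441, "TUBa": 0.2268,
            "TUBb": 0.2176,
        },
        "shoots": {
            "60s": 0.4857, "ABC": 0.6269, "Act27": 0.6418, "Act11": 0.5537,
            "CDPK": 0.9915, "CYP2": 0.6573, "ELF1a": 0.6186, "ELF1b": 0.5209,
            "Fbox": 0.4538, "IDE": 0.5967, "SUBI2": 1.2082, "TUBa": 1.0299,
            "TUBb": 0.8387,
        },
        "both": {
            "60s": 0.5346, "ABC": 0.6452, "Act27": 0.7222, "Act11": 0.6363,
            "CDPK": 0.7685, "CYP2": 0.8326, "ELF1a": 0.8439, "ELF1b": 0.6804,
            "Fbox": 0.4943, "IDE": 0.5913, "SUBI2": 1.1174, "TUBa": 0.8549,
            "TUBb": 0.7954,
        },
    },
    "salt": {
        "roots": {
            "60s": 0.3015, "ABC": 0.2896, "Act27": 0.3128, "Act11": 0.3823,
            "CDPK": 0.6666, "CYP2": 0.3622, "ELF1a": 0.3238, "ELF1b": 0.2656,
            "Fbox": 0.3489, "IDE": 0.2743, "SUBI2": 0.5667, "TUBa": 0.2998,
            "TUBb": 0.3212,
        },
        "shoots": {
            "60s": 0.3537, "ABC": 0.4840, "Act27": 0.7563, "Act11": 0.4164,
            "CDPK": 0.7199, "CYP2": 0.3792, "ELF1a": 0.4713, "ELF1b": 0.3277,
            "Fbox": 0.3268, "IDE": 0.4947, "SUBI2": 0.6558, "TUBa": 0.5392,
            "TUBb": 0.7498,
        },
        "both": {
            "60s": 0.3579, "ABC": 0.4180, "Act27": 0.5739, "Act11": 0.4384,
            "CDPK": 0.6857, "CYP2": 0.5192, "ELF1a": 0.4462, "ELF1b": 0.4703,
            "Fbox": 0.3707, "IDE": 0.4441, "SUBI2": 0.6179, "TUBa": 0.4750,
            "TUBb": 0.5985,
        },
    },
    "cold": {
        "roots": {
            "60s": 0.2196, "ABC": 0.2441, "Act27": 0.2424, "Act11": 0.2726,
            "CDPK": 0.5454, "CYP2": 0.2449, "ELF1a": 0.2968, "ELF1b": 0.2448,
            "Fbox": 0.2404, "IDE": 0.2180, "SUBI2": 0.2898, "TUBa": 0.2779,
            "TUBb": 0.2936,
        },
        "shoots": {
            "60s": 0.2579, "ABC": 0.2647, "Act27": 0.2564, "Act11": 0.3457,
            "CDPK": 0.5116, "CYP2": 0.3092, "ELF1a": 0.3152, "ELF1b": 0.2706,
            "Fbox": 0.2382, "IDE": 0.2991, "SUBI2": 0.3859, "TUBa": 0.3671,
            "TUBb": 0.3724,
        },
        "both": {
            "60s": 0.2778, "ABC": 0.3557, "Act27": 0.4209, "Act11": 0.3707,
            "CDPK": 0.5909, "CYP2": 0.3632, "ELF1a": 0.4136, "ELF1b": 0.3563,
            "Fbox": 0.3120, "IDE": 0.3497, "SUBI2": 0.8414, "TUBa": 0.3670,
            "TUBb": 0.3851,
        },
    },
    "ABA": {
        "roots": {
            "60s": 0.3653, "ABC": 0.4050, "Act27": 0.5245, "Act11": 0.4838,
            "CDPK": 0.5288, "CYP2": 0.4226, "ELF1a": 0.4192, "ELF1b": 0.3987,
            "Fbox": 0.4435, "IDE": 0.4787, "SUBI2": 0.9597, "TUBa": 0.5854,
            "TUBb": 0.5330,
        },
        "shoots": {
            "60s": 0.3420, "ABC": 0.3278, "Act27": 0.5056, "Act11": 0.3282,
            "CDPK": 0.3292, "CYP2": 0.3485, "ELF1a": 0.3944, "ELF1b": 0.2959,
            "Fbox": 0.3221, "IDE": 0.3714, "SUBI2": 0.4756, "TUBa": 0.3893,
            "TUBb": 0.3625,
        },
        "both": {
            "60s": 0.3996, "ABC": 0.4318, "Act27": 0.5560, "Act11": 0.4563,
            "CDPK": 0.4780, "CYP2": 0.4756, "ELF1a": 0.4537, "ELF1b": 0.4073,
            "Fbox": 0.4320, "IDE": 0.5126, "SUBI2": 1.1887, "TUBa": 0.6987,
            "TUBb": 0.5416,
        },
    },
}

#: Published recommended pair per condition cell (most stable first).
RECOMMENDED_PAIRS = {
    ("dehydration", "roots"): ("Fbox", "ABC"),
    ("dehydration", "shoots"): ("Fbox", "60s"),
    ("dehydration", "both"): ("Fbox", "60s"),
    ("salt", "roots"): ("ELF1b", "IDE"),
    ("salt", "shoots"): ("Fbox", "ELF1b"),
    ("salt", "both"): ("60s", "Fbox"),
    ("cold", "roots"): ("IDE", "60s"),
    ("cold", "shoots"): ("Fbox", "Act27"),
    ("cold", "both"): ("60s", "Fbox"),
    ("ABA", "roots"): ("60s", "ELF1b"),
    ("ABA", "shoots"): ("ELF1b", "Fbox"),
    ("ABA", "both"): ("60s", "ELF1b"),
    ("all", "roots"): ("ELF1b", "60s"),
    ("all", "shoots"): ("60s", "Fbox"),
    ("all", "both"): ("60s", "Fbox"),
}

#: Validation fold changes of four dehydration-inducible GmNAC targets,
#: normalised against SUBI2 (unstable), 60s and Fbox (stable).
#: {target: {tissue: {condition: {scheme: fold_change}}}}
VALIDATION_FOLD_CHANGES = {
    "GmNAC19": {
        "root": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 1.26, "60s": 2.49, "Fbox": 2.58},
            "dry 10 h": {"SUBI2": 1.78, "60s": 2.32, "Fbox": 3.22},
        },
        "shoot": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 0.96, "60s": 3.13, "Fbox": 3.75},
            "dry 10 h": {"SUBI2": 1.12, "60s": 18.66, "Fbox": 13.93},
        },
    },
    "GmNAC43": {
        "root": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 1.50, "60s": 3.06, "Fbox": 3.18},
            "dry 10 h": {"SUBI2": 1.68, "60s": 3.06, "Fbox": 4.24},
        },
        "shoot": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 17.26, "60s": 25.42, "Fbox": 30.51},
            "dry 10 h": {"SUBI2": 25.69, "60s": 101.32, "Fbox": 75.61},
        },
    },
    "GmNAC85": {
        "root": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 3.06, "60s": 6.23, "Fbox": 6.46},
            "dry 10 h": {"SUBI2": 4.96, "60s": 9.02, "Fbox": 12.50},
        },
        "shoot": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 58.75, "60s": 86.51, "Fbox": 103.83},
            "dry 10 h": {"SUBI2": 139.24, "60s": 549.09, "Fbox": 409.76},
        },
    },
    "GmNAC92": {
        "root": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 1.22, "60s": 2.49, "Fbox": 2.58},
            "dry 10 h": {"SUBI2": 1.28, "60s": 2.32, "Fbox": 3.22},
        },
        "shoot": {
            "0 h": {"SUBI2": 1.00, "60s": 1.00, "Fbox": 1.00},
            "dry 2 h": {"SUBI2": 2.12, "60s": 3.13, "Fbox": 3.75},
            "dry 10 h": {"SUBI2": 4.73, "60s": 18.66, "Fbox": 13.93},
        },
    },
}


def validation_frames():
    """The validation fold changes as one DataFrame per reference scheme.

    Returns a list of DataFrames with columns (target, tissue, condition,
    scheme, fold_change), suitable for
    :func:`refstab.quantify.reference_consistency`.
    """
    import pandas as pd

    schemes: dict[str, list[dict]] = {}
    for target, tissues in VALIDATION_FOLD_CHANGES.items():
        for tissue, conds in tissues.items():
            for cond, by_scheme in conds.items():
                for scheme, fc in by_scheme.items():
                    schemes.setdefault(scheme, []).append(
                        {
                            "target": target,
                            "tissue": tissue,
                            "condition": cond,
                            "scheme": scheme,
                            "fold_change": fc,
                        }
                    )
    return [pd.DataFrame(rows) for rows in schemes.values()]
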