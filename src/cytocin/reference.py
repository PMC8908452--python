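"""Published cohort summary tables used as validation inputs.

These are the printed group-level summaries of an occupational biomonitoring
study of 34 farmers chronically exposed to pesticide mixtures and 34 matched
unexposed controls: per-pair event counts with group metaphase totals, carrier
counts per aberration category, and the FISH CIN group means. Only printed
summary numbers are bundled (no per-nucleus or per-metaphase raw data were
deposited); the synthetic cohort generator uses the CIN means as its default
targets, and the validation suite recomputes the printed percentages and
grand totals from these counts.
"""

from __future__ import annotations

N_PER_GROUP = 34

#: total metaphases karyotyped per group
EXPOSED_METAPHASE_TOTAL = 1493
UNEXPOSED_METAPHASE_TOTAL = 1061

#: per paired individual: total CV + CA events (34 pairs, exposed / unexposed)
EXPOSED_PAIR_EVENT_COUNTS = (
    138, 89, 109, 109, 65, 60, 105, 43, 4, 5, 3, 54, 62, 5, 15, 0, 42,
    101, 52, 45, 31, 43, 14, 28, 30, 23, 72, 13, 26, 16, 6, 12, 16, 35,
)
UNEXPOSED_PAIR_EVENT_COUNTS = (
    14, 6, 14, 7, 21, 4, 10, 14, 2, 6, 5, 28, 10, 8, 8, 5, 8, 5, 4, 0,
    1, 10, 0, 7, 2, 1, 0, 2, 1, 2, 0, 2, 1, 1,
)

#: carriers (individuals with >= 1 event) per category: (exposed, unexposed)
CARRIER_COUNTS = {
    "monosomies": (32, 13),
    "trisomies": (26, 3),
    "scas": (27, 8),
    "chtb_chrb": (25, 14),
    "fra_other": (16, 10),
    "fra_9q12": (32, 17),
    "cv_1qh": (20, 4),
    "cv_9qh": (8, 4),
    "cv_inv9": (7, 1),
    "cv_16qh": (9, 0),
}

#: group event totals by broad class: (exposed, unexposed)
GROUP_EVENT_TOTALS = {
    "numerical": (384, 43),
    "structural": (88, 13),
    "fragilities": (625, 97),
    "breaks": (107, 26),
    "heteromorphisms": (267, 30),
}

#: FISH CIN percentage, group (mean, SD)
CIN_SUMMARY = {"exposed": (34.57, 6.03), "unexposed": (6.48, 3.13)}

#: metaphases analysed per individual ranged from 19 (all-normal screens)
#: to 95 (when alterations were found)
METAPHASES_PER_INDIVIDUAL_RANGE = (19, 95)

#: cohort demographics: (exposed, unexposed)
AGE_MEAN_SD = ((46.64, 12.13), (47.11, 11.24))
SEX_MALE_FEMALE = ((20, 14), (20, 14))
EXPOSURE_MONTHS_MEAN_SD = (133.2, 126.6)
SMOKERS = (4, 4)
DRINKERS = (25, 17)
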