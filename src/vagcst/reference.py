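"""Bundled summary statistics from a published five-cohort 16S V4 survey.

A 2022 intercontinental survey characterized the cervicovaginal microbiomes
of 151 women from five ethnic cohorts — African American (AA, n=28),
Afro-Caribbean (AC, n=18), Asian Indonesian (AI, n=36), African Kenyan
(AK, n=31) and Caucasian German (CG, n=38). This module carries that
survey's printed per-cohort mean relative abundances (percent, genus level,
top taxa) as a built-in dataset: it anchors the default taxon registry, the
synthetic-cohort archetypes, and the worked examples.

Labels are stored canonical (e.g. the BVAB1 clade appears as
"Candidatus Lachnocurva vaginae"; the SILVA enteric bin as
"Escherichia-Shigella").
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "COHORTS",
    "COHORT_SIZES",
    "THPP_SUMMARY_PANEL",
    "cohort_genus_profiles",
    "overall_profile",
]

COHORTS = ("AA", "AC", "AI", "AK", "CG")

COHORT_SIZES = {"AA": 28, "AC": 18, "AI": 36, "AK": 31, "CG": 38}

#: The six THPP genera whose overall RAs the survey sums in its discussion
#: of pathobiont load (Peptostreptococcus is THPP for classification but is
#: excluded from this particular summary panel).
THPP_SUMMARY_PANEL = (
    "Streptococcus",
    "Escherichia-Shigella",
    "Enterococcus",
    "Staphylococcus",
    "Ureaplasma",
    "Mycoplasma",
)

# mean RA (%) per cohort; genus level except where a genus is monotypic here
_PROFILES = {
    #                          AA      AC      AI      AK      CG
    "Lactobacillus":         (91.8,   26.1,   45.0,   34.4,   42.4),
    "Gardnerella vaginalis": (0.884,  9.91,   6.24,   12.1,   12.8),
    "Prevotella":            (2.11,   21.0,   5.05,   4.52,   12.0),
    "Sneathia":              (0.00,   5.26,   0.001,  9.77,   7.81),
    "Megasphaera":           (0.001,  3.51,   0.307,  2.45,   5.25),
    "Atopobium":             (1.36,   0.909,  0.667,  3.34,   4.34),
    "Anaerococcus":          (0.094,  6.95,   2.84,   2.79,   0.206),
    "Candidatus Lachnocurva vaginae": (0.00, 15.3, 0.00, 1.06, 0.711),
    "Corynebacterium":       (0.00,   0.185,  2.14,   3.50,   0.00),
    "Veillonella":           (0.00,   0.511,  0.069,  0.902,  1.98),
    "Fastidiosipila":        (0.00,   0.620,  0.705,  1.86,   0.758),
    "Bifidobacterium":       (0.00,   0.001,  0.519,  0.151,  1.73),
    "Peptoniphilus":         (0.148,  0.285,  2.29,   0.704,  0.001),
    "Dialister":             (0.394,  1.58,   0.207,  1.10,   0.775),
    "Porphyromonas":         (0.272,  2.08,   0.450,  0.856,  0.480),
    "Gemella":               (0.00,   0.602,  0.247,  0.173,  1.17),
    "Prevotella 6":          (0.001,  1.83,   1.06,   0.360,  0.342),
    "Finegoldia":            (0.315,  0.001,  1.94,   0.478,  0.001),
    "Mobiluncus":            (0.000,  0.001,  1.53,   0.835,  0.001),
    "Parvimonas":            (0.000,  0.088,  0.550,  0.471,  0.560),
    "Moryella":              (0.00,   0.043,  0.572,  1.17,   0.001),
    "Chlamydia":             (0.00,   0.00,   0.00,   0.00,   0.857),
    "Streptococcus":         (0.001,  0.001,  2.02,   4.98,   0.597),
    "Escherichia-Shigella":  (0.00,   0.00,   4.59,   1.08,   0.000),
    "Enterococcus":          (0.00,   0.00,   4.02,   0.512,  0.573),
    "Peptostreptococcus":    (1.64,   0.001,  2.72,   0.184,  0.293),
    "Staphylococcus":        (0.001,  0.001,  2.68,   2.05,   0.038),
    "Ureaplasma":            (0.144,  0.001,  0.084,  1.43,   0.251),
    "Mycoplasma":            (0.00,   0.001,  0.001,  0.310,  0.805),
    "Unassigned":            (0.00,   0.000,  0.730,  0.797,  0.00),
}


def cohort_genus_profiles() -> pd.DataFrame:
    """Published mean RA (%) per cohort: taxa (rows) × cohorts (columns).

    Note: columns cover only the survey's top taxa, so they sum slightly
    below 100; values are kept exactly as printed (no renormalization).
    """
    return pd.DataFrame.from_dict(_PROFILES, orient="index", columns=list(COHORTS))


def overall_profile() -> dict[str, float]:
    """Overall mean RA (%): the unweighted mean of the five cohort columns.

    This equal-weight convention (not the sample-pooled mean) is the one
    under which the survey's overall Lactobacillus RA equals 47.9%.
    """
    df = cohort_genus_profiles()
    return {t: float(v) for t, v in df.mean(axis=1).items()}
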