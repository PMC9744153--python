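"""Synthetic vaginal-microbiome cohorts with realistic CST structure.

Two generators live here:

1. **Constraint-based fixtures** (:func:`fixtures_from_descriptions`):
   deterministic compositions realizing textual cluster descriptions of the
   form "*G. vaginalis* 44%, *Atopobium* 32%, ...". Point values are
   asserted exactly, one-sided/interval bounds are drawn inside their
   range, the row's named head taxon is kept strictly the most abundant,
   and the slack is spread over a pool of heterogeneous vaginal taxa at
   < 7% each. :func:`reference_cohort_fixtures` instantiates the bundled
   151-sample five-cohort blueprint this way — the fixtures carry no CST
   labels, which must be recovered by the classifier.

2. **Dirichlet-multinomial cohorts** (:func:`simulate_cohort`): each sample
   draws a CST from its group's frequency vector, a composition from a
   Dirichlet centred on that CST's archetype profile (precision =
   ``concentration``), a read depth from a negative binomial, and counts
   from a multinomial. This is the minimal generative model carrying the
   structure the analyses assume — dominance, heterogeneous tails,
   competitive exclusion between lactobacilli and anaerobes, count noise.
   It does not emulate sequencing artefacts (chimeras, misassignment) or
   longitudinal CST transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, Composition
from .registry import TaxonRegistry, default_registry

__all__ = [
    "FixtureConstraint",
    "fixtures_from_descriptions",
    "reference_cohort_constraints",
    "reference_cohort_fixtures",
    "ArchetypeSpec",
    "cst_archetypes",
    "CohortSpec",
    "default_cohort_spec",
    "simulate_cohort",
    "HETEROGENEOUS_POOL",
]

#: Low-abundance "heterogeneous bacteria" used to fill compositional slack
#: (each kept below 7%); deliberately excludes Lactobacillus, Gardnerella,
#: Prevotella and THPP taxa so the fill never changes a sample's CST.
HETEROGENEOUS_POOL = (
    "Sneathia",
    "Megasphaera",
    "Atopobium",
    "Dialister",
    "Parvimonas",
    "Finegoldia",
    "Peptoniphilus",
    "Mobiluncus",
    "Corynebacterium",
    "Porphyromonas",
    "Moryella",
    "Fastidiosipila",
    "Gemella",
    "Veillonella",
    "Anaerococcus",
)

TAIL_CAP = 0.069  # strict "< 7%" per-taxon ceiling for heterogeneous fill
_EPS = 1e-3


@dataclass(frozen=True)
class FixtureConstraint:
    """RA assertions for one community description.

    ``bounds`` maps taxon -> (lo, hi) as fractions; lo == hi asserts an
    exact value. ``top`` names the taxon the description calls most
    abundant; the realizer draws it strictly above every other constrained
    taxon and above the heterogeneous fill.
    """

    bounds: Mapping[str, tuple[float, float]]
    top: str
    note: str = ""

    def __post_init__(self):
        if self.top not in self.bounds:
            raise ValueError(f"top taxon {self.top!r} not among bounds")
        lo_sum = 0.0
        for t, (lo, hi) in self.bounds.items():
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"invalid bounds for {t!r}: ({lo}, {hi})")
            lo_sum += lo
        if lo_sum > 1 + 1e-12:
            raise ValueError(
                f"unsatisfiable constraint: lower bounds sum to {lo_sum:.3f} > 1"
            )

    def validate(self, c: Composition) -> None:
        """Raise if ``c`` violates any assertion of this constraint."""
        for t, (lo, hi) in self.bounds.items():
            v = c[t]
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise AssertionError(f"{t}={v:.4f} outside [{lo}, {hi}]")
        if max(c.ra, key=lambda t: c.ra[t]) != self.top:
            raise AssertionError(f"{self.top!r} is not the most abundant taxon")


def _fill_tail(remainder: float, cap: float, pool: Sequence[str], rng) -> dict[str, float]:
    """Spread ``remainder`` over pool taxa, each strictly below ``cap``."""
    if remainder <= 1e-12:
        return {}
    k = max(2, math.ceil(remainder / (0.9 * cap)))
    if k > len(pool):
        k = len(pool)
        if k * cap <= remainder:
            raise ValueError("heterogeneous pool too small for remainder")
    taxa = [str(t) for t in rng.choice(pool, size=k, replace=False)]
    w = rng.dirichlet(np.full(k, 2.0)) * remainder
    for _ in range(10):  # water-filling: converges in <= 2 passes
        over = w > cap
        if not over.any():
            break
        excess = float((w[over] - cap).sum())
        w[over] = cap
        head = cap - w
        w = w + head * (excess / head.sum())
    w[np.argmin(w)] += remainder - w.sum()  # absorb float residue
    return dict(zip(taxa, w.tolist()))


def _realize(con: FixtureConstraint, sample_id: str, rng) -> Composition:
    others = [t for t in con.bounds if t != con.top]
    t_lo, t_hi = con.bounds[con.top]
    lo = max([t_lo] + [con.bounds[t][0] + _EPS for t in others])
    if lo > t_hi + 1e-12:
        raise ValueError(
            f"constraint {con.note or con.top!r}: head taxon bound "
            f"[{t_lo}, {t_hi}] cannot exceed co-taxon lower bounds"
        )
    vals = {con.top: t_lo if t_lo == t_hi else float(rng.uniform(lo, t_hi))}
    for t in others:
        o_lo, o_hi = con.bounds[t]
        if o_lo == o_hi:
            if o_lo >= vals[con.top]:
                raise ValueError(f"exact bound {t}={o_lo} not below top value")
            vals[t] = o_lo
        else:
            hi = min(o_hi, vals[con.top] - _EPS)
            if o_lo > hi:
                raise ValueError(f"bounds for {t!r} infeasible below the top taxon")
            vals[t] = float(rng.uniform(o_lo, hi))
    total = sum(vals.values())
    if total > 1 + 1e-9:
        raise ValueError(f"drawn values sum to {total:.3f} > 1 for {con.note!r}")
    cap = min(TAIL_CAP, vals[con.top] - _EPS)
    pool = [t for t in HETEROGENEOUS_POOL if t not in vals]
    tail = _fill_tail(1.0 - total, cap, pool, rng)
    vals.update(tail)
    return Composition(sample_id, {t: v for t, v in vals.items() if v > 0})


def fixtures_from_descriptions(
    constraints: Sequence[FixtureConstraint],
    seed: int,
    sample_ids: Sequence[str] | None = None,
) -> list[Composition]:
    """Realize one composition per constraint; deterministic per seed.

    Every output satisfies every assertion of its constraint (checked);
    compositions sum to 1 and carry no CST label.
    """
    rng = np.random.default_rng(seed)
    ids = sample_ids or [f"S{i:04d}" for i in range(len(constraints))]
    if len(ids) != len(constraints):
        raise ValueError("sample_ids length mismatch")
    out = []
    for con, sid in zip(constraints, ids):
        c = _realize(con, sid, rng)
        con.validate(c)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# the bundled 151-sample five-cohort blueprint
#
# One entry per published cluster-description row: (bounds, top taxon,
# per-cohort instance counts). Point values are exact assertions; open
# ranges (">98.9%") are realized inside a feasible closed interval.

_LC = "Lactobacillus crispatus"
_LG = "Lactobacillus gasseri"
_LI = "Lactobacillus iners"
_GV = "Gardnerella vaginalis"
_PR = "Prevotella"
_CLV = "Candidatus Lachnocurva vaginae"
_ES = "Escherichia-Shigella"

_BLUEPRINT: list[tuple[dict, str, dict[str, int]]] = [
    # --- L. crispatus predominant (>= 50%) -------------------------------
    ({_LC: (0.989, 0.999)}, _LC, {"AA": 5, "AC": 1, "AK": 2, "CG": 4}),
    ({_LC: (0.97, 0.985), _PR: (0.005, 0.012)}, _LC, {"AA": 2}),
    ({_LC: (0.971, 0.975), _GV: (0.021, 0.024)}, _LC, {"CG": 1}),
    ({_LC: (0.925, 0.96), _LI: (0.005, 0.02)}, _LC, {"AA": 5, "AI": 2, "AK": 1}),
    ({_LC: (0.665, 0.68), _LI: (0.30, 0.315)}, _LC, {"AI": 1}),
    ({_LC: (0.55, 0.56), _LI: (0.40, 0.41)}, _LC, {"AC": 1}),
    ({_LC: (0.905, 0.93), _LI: (0.041, 0.05), "Corynebacterium": (0.010, 0.015)}, _LC, {"AI": 1}),
    ({_LC: (0.575, 0.60), "Atopobium": (0.205, 0.24), _GV: (0.141, 0.155)}, _LC, {"AA": 2}),
    (
        {_LC: (0.865, 0.885), _GV: (0.051, 0.06), "Streptococcus": (0.025, 0.03),
         "Staphylococcus": (0.016, 0.02)},
        _LC, {"AI": 1},
    ),
    ({_LC: (0.865, 0.90), _LI: (0.031, 0.04)}, _LC, {"CG": 1}),
    (
        {_LC: (0.805, 0.83), "Bifidobacterium": (0.063, 0.07), "Enterococcus": (0.052, 0.06)},
        _LC, {"AI": 1},
    ),
    (
        {_LC: (0.805, 0.83), "Bifidobacterium": (0.063, 0.07), "Streptococcus": (0.031, 0.04)},
        _LC, {"AI": 1},
    ),
    ({_LC: (0.80, 0.86), _GV: (0.081, 0.10)}, _LC, {"CG": 1}),
    # --- L. gasseri predominant ------------------------------------------
    ({_LG: (0.52, 0.52), _LI: (0.43, 0.43)}, _LG, {"AI": 1}),
    # --- L. iners predominant --------------------------------------------
    ({_LI: (0.98, 0.995)}, _LI, {"AA": 2, "AC": 2, "AI": 1, "AK": 6, "CG": 1}),
    ({_LI: (0.905, 0.95), _LC: (0.016, 0.03)}, _LI, {"AA": 3, "AK": 1, "CG": 1}),
    ({_LI: (0.60, 0.75), _LC: (0.241, 0.245)}, _LI, {"AA": 2}),
    ({_LI: (0.805, 0.88), _LG: (0.028, 0.115)}, _LI, {"AA": 4}),
    ({_LI: (0.80, 0.92)}, _LI, {"AI": 3, "CG": 1}),
    ({_LI: (0.72, 0.72), "Unassigned": (0.25, 0.25)}, _LI, {"AI": 1}),
    ({_LI: (0.805, 0.86), _GV: (0.04, 0.10)}, _LI, {"AC": 1, "CG": 4}),
    ({_LI: (0.551, 0.60), _GV: (0.251, 0.28), "Atopobium": (0.05, 0.10)}, _LI, {"AA": 2, "CG": 1}),
    (
        {_LI: (0.501, 0.55), "Staphylococcus": (0.05, 0.12), "Streptococcus": (0.05, 0.12),
         "Enterococcus": (0.05, 0.12)},
        _LI, {"AK": 1, "CG": 1},
    ),
    # --- polymicrobial, G. vaginalis most abundant (< 50%) ---------------
    ({_GV: (0.44, 0.44), "Atopobium": (0.32, 0.32), "Veillonella": (0.11, 0.11)}, _GV, {"AK": 1}),
    ({_GV: (0.28, 0.32), _PR: (0.11, 0.15)}, _GV, {"AI": 2, "AK": 1}),
    ({_GV: (0.34, 0.34), _PR: (0.064, 0.064)}, _GV, {"AI": 1}),
    ({_GV: (0.36, 0.36), _PR: (0.25, 0.34), "Atopobium": (0.17, 0.23)}, _GV, {"AK": 2}),
    ({_GV: (0.25, 0.45), _LI: (0.37, 0.44)}, _GV, {"AI": 1, "AK": 1, "CG": 4}),
    (
        {_GV: (0.25, 0.42), _PR: (0.04, 0.10), "Atopobium": (0.04, 0.10),
         "Streptococcus": (0.04, 0.10), "Veillonella": (0.04, 0.10),
         "Anaerococcus": (0.04, 0.10)},
        _GV, {"AK": 4, "CG": 2},
    ),
    (
        {_GV: (0.25, 0.42), _PR: (0.04, 0.10), _CLV: (0.04, 0.10),
         "Megasphaera": (0.04, 0.10), "Sneathia": (0.04, 0.10), _LI: (0.04, 0.10)},
        _GV, {"AK": 1, "CG": 4},
    ),
    # --- polymicrobial, Prevotella most abundant (< 50%) -----------------
    ({_PR: (0.18, 0.18), _LI: (0.03, 0.06), _LC: (0.01, 0.03)}, _PR, {"AI": 3}),
    ({_PR: (0.361, 0.45)}, _PR, {"AC": 2}),
    ({_PR: (0.16, 0.46)}, _PR, {"AC": 1, "AI": 2}),
    (
        {_PR: (0.25, 0.45), _GV: (0.04, 0.12), _CLV: (0.03, 0.08),
         "Megasphaera": (0.03, 0.08), "Sneathia": (0.03, 0.08), _LI: (0.03, 0.08)},
        _PR, {"AC": 2, "CG": 6},
    ),
    (
        {_PR: (0.25, 0.45), _GV: (0.04, 0.12), "Gemella": (0.03, 0.07),
         "Megasphaera": (0.03, 0.07), "Sneathia": (0.03, 0.07), _LI: (0.03, 0.07),
         "Mycoplasma": (0.03, 0.07)},
        _PR, {"AC": 2, "CG": 4},
    ),
    # --- polymicrobial, other taxa most abundant (< 50%) -----------------
    ({_LI: (0.25, 0.45)}, _LI, {"AI": 3}),
    ({"Corynebacterium": (0.27, 0.27)}, "Corynebacterium", {"AI": 1}),
    (
        {"Scardovia wiggsiae": (0.49, 0.49), "Bifidobacterium": (0.47, 0.47)},
        "Scardovia wiggsiae", {"CG": 1},
    ),
    (
        {"Streptococcus": (0.46, 0.46), _LI: (0.13, 0.13), "Sneathia": (0.10, 0.10)},
        "Streptococcus", {"AI": 2},
    ),
    (
        {"Ureaplasma": (0.36, 0.36), _ES: (0.33, 0.33), "Staphylococcus": (0.16, 0.16)},
        "Ureaplasma", {"AK": 1},
    ),
    (
        {"Clostridiales bacterium": (0.34, 0.34), _CLV: (0.16, 0.16),
         "Veillonella": (0.066, 0.066)},
        "Clostridiales bacterium", {"AK": 1},
    ),
    (
        {"Peptostreptococcus": (0.28, 0.28), _PR: (0.25, 0.25), _LI: (0.13, 0.13)},
        "Peptostreptococcus", {"AA": 1},
    ),
    # --- G. vaginalis dominant (>= 50%) ----------------------------------
    ({_GV: (0.53, 0.53), _LI: (0.47, 0.47)}, _GV, {"AC": 1, "AK": 1}),
    (
        {_GV: (0.601, 0.66), "Sneathia": (0.03, 0.07), _CLV: (0.03, 0.07),
         "Megasphaera": (0.03, 0.07), "Atopobium": (0.03, 0.07), "Aerococcus": (0.02, 0.05)},
        _GV, {"AC": 1, "AK": 1},
    ),
    ({_GV: (0.54, 0.54), "Streptococcus": (0.45, 0.45)}, _GV, {"AI": 1}),
    ({_GV: (0.68, 0.68), _LG: (0.22, 0.22)}, _GV, {"AI": 1}),
    # --- Prevotella dominant ---------------------------------------------
    ({_PR: (0.701, 0.80)}, _PR, {"AC": 1}),
    # --- THPP dominant ----------------------------------------------------
    (
        {"Streptococcus": (0.60, 0.60), "Sneathia": (0.23, 0.23), _GV: (0.09, 0.09)},
        "Streptococcus", {"AK": 1},
    ),
    ({"Streptococcus": (0.851, 0.92)}, "Streptococcus", {"AK": 2}),
    ({"Peptostreptococcus": (0.54, 0.54)}, "Peptostreptococcus", {"AI": 1}),
    ({"Enterococcus": (0.801, 0.84), "Bacilli": (0.15, 0.15)}, "Enterococcus", {"AI": 1}),
    (
        {"Staphylococcus": (0.65, 0.86), _LI: (0.02, 0.05), _ES: (0.02, 0.05)},
        "Staphylococcus", {"AI": 2},
    ),
    (
        {_ES: (0.88, 0.88), _LI: (0.05, 0.05), "Anaerococcus": (0.02, 0.05)},
        _ES, {"AI": 1, "AK": 1},
    ),
    # --- other genera dominant -------------------------------------------
    ({"Finegoldia": (0.71, 0.71)}, "Finegoldia", {"AI": 1}),
    ({"Anaerococcus": (0.93, 0.93), "Howardella": (0.05, 0.05)}, "Anaerococcus", {"AC": 1}),
    (
        {"Anaerococcus": (0.62, 0.62), _GV: (0.26, 0.26), "Veillonella": (0.047, 0.047),
         _PR: (0.02, 0.02)},
        "Anaerococcus", {"AK": 1},
    ),
    ({_CLV: (0.80, 0.90), _GV: (0.02, 0.062)}, _CLV, {"AC": 2}),
    (
        {"Ralstonia": (0.511, 0.60), "Corynebacterium": (0.09, 0.09),
         "Staphylococcus": (0.02, 0.05), "Streptococcus": (0.02, 0.05)},
        "Ralstonia", {"AK": 1},
    ),
    ({"Bifidobacterium": (0.981, 0.995)}, "Bifidobacterium", {"CG": 1}),
]


def reference_cohort_constraints() -> list[tuple[FixtureConstraint, str]]:
    """Flattened blueprint: one (constraint, cohort) pair per sample (151)."""
    out = []
    for i, (bounds, top, counts) in enumerate(_BLUEPRINT):
        con = FixtureConstraint(bounds, top, note=f"row{i:02d}:{top}")
        for grp, n in counts.items():
            out.extend((con, grp) for _ in range(n))
    return out


def reference_cohort_fixtures(seed: int = 0) -> tuple[list[Composition], pd.Series]:
    """The bundled 151-sample cohort as unlabeled compositions + metadata."""
    flat = reference_cohort_constraints()
    per_group: dict[str, int] = {}
    ids, groups = [], []
    for _, grp in flat:
        per_group[grp] = per_group.get(grp, 0) + 1
        ids.append(f"{grp}-{per_group[grp]:03d}")
        groups.append(grp)
    comps = fixtures_from_descriptions([c for c, _ in flat], seed, ids)
    meta = pd.Series(groups, index=pd.Index(ids, name="sample_id"), name="group")
    return comps, meta


# ---------------------------------------------------------------------------
# Dirichlet-multinomial cohort simulation


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative archetype for one CST: mean profile + Dirichlet precision."""

    cst: str
    mean_profile: Mapping[str, float]
    concentration: float = 50.0
    dominant_constraint: tuple[str, float, float] | None = None

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        total = sum(self.mean_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype {self.cst}: mean profile sums to {total:.6g}")


_ARCHETYPE_MEANS: dict[str, dict[str, float]] = {
    "I": {_LC: 0.90, _LI: 0.04, _GV: 0.01, "Atopobium": 0.01, _PR: 0.01,
          "Sneathia": 0.01, "Megasphaera": 0.01, "Corynebacterium": 0.01},
    "II": {_LG: 0.60, _LI: 0.28, _LC: 0.02, "Atopobium": 0.03, _PR: 0.03,
           _GV: 0.02, "Streptococcus": 0.02},
    "III": {_LI: 0.85, _LC: 0.04, _GV: 0.04, _PR: 0.03, "Atopobium": 0.02,
            "Sneathia": 0.02},
    "IV-A": {_GV: 0.38, _LI: 0.12, _PR: 0.10, "Atopobium": 0.10, "Sneathia": 0.08,
             "Megasphaera": 0.07, _CLV: 0.06, "Veillonella": 0.05, "Anaerococcus": 0.04},
    "IV-B": {_PR: 0.36, _GV: 0.10, _LI: 0.10, _CLV: 0.08, "Megasphaera": 0.08,
             "Sneathia": 0.08, "Atopobium": 0.06, "Dialister": 0.05,
             "Anaerococcus": 0.05, "Gemella": 0.04},
    "IV-C": {_LI: 0.33, "Streptococcus": 0.12, "Corynebacterium": 0.10,
             "Bifidobacterium": 0.09, "Ureaplasma": 0.08, "Anaerococcus": 0.08,
             "Peptoniphilus": 0.06, "Finegoldia": 0.05, "Atopobium": 0.05,
             _GV: 0.02, _PR: 0.02},
    "VI": {_GV: 0.65, _LI: 0.10, "Atopobium": 0.06, _PR: 0.05, "Sneathia": 0.05,
           "Megasphaera": 0.04, _CLV: 0.05},
    "VII": {_PR: 0.72, _GV: 0.06, _LI: 0.05, "Sneathia": 0.05, "Megasphaera": 0.04,
            "Atopobium": 0.04, "Dialister": 0.04},
    "VIII": {"Streptococcus": 0.66, "Enterococcus": 0.08, "Staphylococcus": 0.07,
             _ES: 0.06, _LI: 0.05, "Sneathia": 0.04, _GV: 0.04},
    "IX": {"Anaerococcus": 0.70, _GV: 0.08, "Bifidobacterium": 0.06,
           "Veillonella": 0.05, "Finegoldia": 0.04, _PR: 0.03, _LI: 0.04},
}

_DOMINANT_TAXON = {
    "I": _LC, "II": _LG, "III": _LI, "IV-A": _GV, "IV-B": _PR, "IV-C": _LI,
    "VI": _GV, "VII": _PR, "VIII": "Streptococcus", "IX": "Anaerococcus",
}


def cst_archetypes(concentration: float = 50.0) -> dict[str, ArchetypeSpec]:
    """Built-in archetypes, one per CST in {I, II, III, IV-A/B/C, VI–IX}.

    Dominant-taxon means sit inside the abundance ranges the published
    cluster descriptions report for each CST; the default precision of 50
    puts the dominant taxon's standard deviation near 0.05–0.07.
    """
    out = {}
    for cst, mean in _ARCHETYPE_MEANS.items():
        dom = _DOMINANT_TAXON[cst]
        lo, hi = (0.5, 1.0) if cst not in ("IV-A", "IV-B", "IV-C") else (0.0, 0.5)
        out[cst] = ArchetypeSpec(cst, dict(mean), concentration, (dom, lo, hi))
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Multi-group cohort description: sizes, CST frequencies, depth model."""

    groups: Mapping[str, tuple[int, Mapping[str, float]]]
    depth_mean: float = 120_000.0
    depth_dispersion: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for g, (n, freqs) in self.groups.items():
            if n < 1:
                raise ValueError(f"group {g!r}: n_samples must be >= 1")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {g!r}: CST frequencies sum to {total:.6g}")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"group {g!r}: negative CST frequency")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Five groups with the bundled survey's per-cohort sizes and CST mix."""

    def f(counts: dict[str, int], n: int) -> dict[str, float]:
        return {cst: c / n for cst, c in counts.items()}

    return CohortSpec(
        groups={
            "AA": (28, f({"I": 14, "III": 13, "IV-C": 1}, 28)),
            "AC": (18, f({"I": 2, "III": 3, "IV-B": 7, "VI": 2, "VII": 1, "IX": 3}, 18)),
            "AI": (36, f({"I": 7, "II": 1, "III": 5, "IV-A": 4, "IV-B": 5,
                          "IV-C": 6, "VI": 2, "VIII": 5, "IX": 1}, 36)),
            "AK": (31, f({"I": 3, "III": 8, "IV-A": 10, "IV-C": 2, "VI": 2,
                          "VIII": 4, "IX": 2}, 31)),
            "CG": (38, f({"I": 7, "III": 9, "IV-A": 10, "IV-B": 10, "IV-C": 1,
                          "IX": 1}, 38)),
        },
        seed=seed,
    )


def simulate_cohort(
    spec: CohortSpec,
    archetypes: Mapping[str, ArchetypeSpec] | None = None,
    registry: TaxonRegistry | None = None,
) -> tuple[AbundanceTable, pd.DataFrame, pd.Series]:
    """Draw a counts-mode cohort; returns (table, truth labels, metadata).

    Per sample: CST ~ group frequencies; composition ~ Dirichlet
    (concentration x archetype mean); depth ~ negative binomial
    (``depth_mean``, ``depth_dispersion``); counts ~ multinomial. The
    whole draw is a deterministic function of ``spec.seed``.
    """
    archetypes = archetypes or cst_archetypes()
    registry = registry or default_registry()
    rng = np.random.default_rng(spec.seed)
    taxa = sorted({t for a in archetypes.values() for t in a.mean_profile})
    taxa = [registry.canonicalize(t).canonical for t in taxa]
    rows, truth, groups_out, ids = [], [], [], []
    for grp in spec.groups:
        n, freqs = spec.groups[grp]
        csts = list(freqs)
        probs = np.array([freqs[c] for c in csts])
        for i in range(n):
            cst = csts[rng.choice(len(csts), p=probs)]
            arch = archetypes[cst]
            mean = np.array([arch.mean_profile.get(t, 0.0) for t in taxa])
            alpha = arch.concentration * mean
            comp = np.zeros(len(taxa))
            nz = alpha > 0
            comp[nz] = rng.dirichlet(alpha[nz])
            r = spec.depth_dispersion
            depth = int(rng.negative_binomial(r, r / (r + spec.depth_mean))) or 1
            counts = rng.multinomial(depth, comp)
            sid = f"{grp}-{i + 1:03d}"
            ids.append(sid)
            rows.append(counts)
            truth.append(cst)
            groups_out.append(grp)
    df = pd.DataFrame(
        np.array(rows, dtype=float), index=pd.Index(ids, name="sample_id"), columns=taxa
    )
    table = AbundanceTable(df, mode="counts")
    truth_df = pd.DataFrame({"sample_id": ids, "group": groups_out, "true_cst": truth})
    meta = pd.Series(groups_out, index=pd.Index(ids, name="sample_id"), name="group")
    return table, truth_df, meta
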