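"""Normality-gated correlation analysis between functional-group abundances.

The workflow mirrors how microbiome surveys relate the lactic-acid
producers (*Lactobacillus* spp.), the biofilm-forming obligate anaerobes
(*Gardnerella*, *Prevotella*) and the pathobiont panel (THPP): each
variable is a per-sample aggregate RA; Shapiro–Wilk decides between
Pearson (both variables consistent with normality at alpha = 0.05) and
Spearman; 95% confidence intervals come from the Fisher z transform
(Pearson) or a seeded bootstrap (Spearman). Coefficients are banded as
strong (|r| >= 0.50), moderate (0.30–0.49) or weak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .registry import TaxonGroup, TaxonRegistry

__all__ = [
    "GroupVariable",
    "CorrelationResult",
    "NormalityReport",
    "standard_variables",
    "variable_values",
    "choose_correlation_method",
    "correlate",
    "correlate_groups",
    "strength_band",
]

SPEARMAN_BOOTSTRAP = 2000


@dataclass(frozen=True)
class GroupVariable:
    """A named per-sample aggregate: the summed RA of a taxon panel."""

    name: str
    taxa: tuple[str, ...]


@dataclass(frozen=True)
class NormalityReport:
    w_x: float
    p_x: float
    w_y: float
    p_y: float
    alpha: float


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    method: Literal["pearson", "spearman"]
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    band: str
    normality: NormalityReport | None = None


def standard_variables(registry: TaxonRegistry) -> dict[str, GroupVariable]:
    """The survey's standard aggregates, derived from the registry groups."""
    lacto = tuple(sorted(registry.members(TaxonGroup.LACTOBACILLUS)))
    prev = tuple(sorted(registry.members(TaxonGroup.PREVOTELLA)))
    thpp = tuple(sorted(registry.members(TaxonGroup.THPP)))
    return {
        "Lactobacillus": GroupVariable("Lactobacillus", lacto),
        "Gardnerella": GroupVariable("Gardnerella", ("Gardnerella vaginalis",)),
        "Prevotella": GroupVariable("Prevotella", prev),
        "Gardnerella+Prevotella": GroupVariable(
            "Gardnerella+Prevotella", ("Gardnerella vaginalis",) + prev
        ),
        "THPP": GroupVariable("THPP", thpp),
        "M. hominis": GroupVariable("M. hominis", ("Mycoplasma",)),
        "Bifidobacterium": GroupVariable("Bifidobacterium", ("Bifidobacterium",)),
    }


def variable_values(table: AbundanceTable, var: GroupVariable) -> pd.Series:
    """Per-sample value of an aggregate variable (absent taxa contribute 0)."""
    if table.mode != "relative":
        raise ValueError("aggregate variables require relative mode")
    cols = [t for t in var.taxa if t in table.data.columns]
    vals = table.data[cols].sum(axis=1) if cols else pd.Series(0.0, index=table.data.index)
    vals.name = var.name
    return vals


def strength_band(r: float) -> str:
    a = abs(r)
    if a >= 0.50:
        return "strong"
    if a >= 0.30:
        return "moderate"
    return "weak"


def choose_correlation_method(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[Literal["pearson", "spearman"], NormalityReport]:
    """Shapiro–Wilk gate: Pearson iff both variables pass at ``alpha``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need n >= 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: normality and correlation undefined")
    wx, px = stats.shapiro(x)
    wy, py = stats.shapiro(y)
    report = NormalityReport(float(wx), float(px), float(wy), float(py), alpha)
    method = "pearson" if (px > alpha and py > alpha) else "spearman"
    return method, report


def _fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return float("nan"), float("nan")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + conf / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def _spearman_bootstrap_ci(
    x: np.ndarray, y: np.ndarray, seed: int, n_boot: int = SPEARMAN_BOOTSTRAP
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(x)
    rs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            rs[b] = np.nan
            continue
        rs[b] = stats.spearmanr(xb, yb).statistic
    rs = rs[np.isfinite(rs)]
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return float(lo), float(hi)


def correlate(
    x: pd.Series | Sequence[float],
    y: pd.Series | Sequence[float],
    name_x: str = "x",
    name_y: str = "y",
    alpha: float = 0.05,
    method: Literal["auto", "pearson", "spearman"] = "auto",
    seed: int = 0,
) -> CorrelationResult:
    """Correlate two per-sample variables with the normality-gated method.

    ``method="auto"`` applies the Shapiro–Wilk gate; forcing either method
    skips it. CI: Fisher z for Pearson, percentile bootstrap (seeded,
    2,000 resamples) for Spearman.
    """
    if isinstance(x, pd.Series):
        name_x = x.name or name_x
    if isinstance(y, pd.Series):
        name_y = y.name or name_y
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    report = None
    if method == "auto":
        method, report = choose_correlation_method(xv, yv, alpha)
    elif np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant variable: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(xv, yv)
        r, p = float(res.statistic), float(res.pvalue)
        lo, hi = _fisher_ci(r, len(xv))
    else:
        res = stats.spearmanr(xv, yv)
        r, p = float(res.statistic), float(res.pvalue)
        if abs(r) == 1.0:  # degenerate: all resamples give +-1
            lo, hi = r, r
        else:
            lo, hi = _spearman_bootstrap_ci(xv, yv, seed)
    return CorrelationResult(
        str(name_x), str(name_y), method, r, p, lo, hi, len(xv), strength_band(r), report
    )


def correlate_groups(
    table: AbundanceTable,
    registry: TaxonRegistry,
    pairs: Iterable[tuple[GroupVariable, GroupVariable]],
    alpha: float = 0.05,
    method: Literal["auto", "pearson", "spearman"] = "auto",
    seed: int = 0,
    skip_degenerate: bool = False,
) -> list[CorrelationResult]:
    """Run the correlation battery over aggregate-variable pairs.

    With ``skip_degenerate=True``, pairs where a variable is constant
    (e.g. a panel absent from the whole cohort) are dropped with a warning
    instead of raising.
    """
    import logging

    out = []
    for vx, vy in pairs:
        x = variable_values(table, vx)
        y = variable_values(table, vy)
        try:
            out.append(correlate(x, y, vx.name, vy.name, alpha, method, seed))
        except ValueError:
            if not skip_degenerate:
                raise
            logging.getLogger(__name__).warning(
                "skipping degenerate pair (%s, %s)", vx.name, vy.name
            )
    return out


def results_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "var_x": r.var_x,
                "var_y": r.var_y,
                "method": r.method,
                "n": r.n,
                "r": r.r,
                "p": r.p_value,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "band": r.band,
            }
            for r in results
        ]
    )
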