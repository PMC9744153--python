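"""Alpha/beta diversity and permutation-based group comparison tests.

Shannon diversity (base-2 by default, i.e. bits) summarizes within-sample
richness and evenness; Bray–Curtis dissimilarity is the between-sample
metric; group structure is tested with Kruskal–Wallis (global + all
pairwise, Benjamini–Hochberg adjusted) on per-sample values and with
PERMANOVA (pseudo-F, free permutation of sample labels) on a distance
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable, Composition

__all__ = [
    "shannon_index",
    "shannon_table",
    "DistanceMatrix",
    "bray_curtis_matrix",
    "GroupTestResult",
    "pairwise_group_test",
    "permanova",
]


def shannon_index(c: Composition | Sequence[float], base: float = 2) -> float:
    """Shannon diversity H = -sum(p_i * log_base(p_i)) over taxa with p > 0."""
    p = np.asarray(list(c.ra.values()) if isinstance(c, Composition) else c, dtype=float)
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def shannon_table(table: AbundanceTable, base: float = 2) -> pd.Series:
    """Per-sample Shannon index of a relative-mode table."""
    if table.mode != "relative":
        raise ValueError("shannon_table requires relative mode")
    vals = table.data.values
    logs = np.zeros_like(vals)
    np.log(vals, out=logs, where=vals > 0)
    h = -(vals * logs).sum(axis=1) / np.log(base)
    return pd.Series(h, index=table.data.index, name="shannon")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="sample_id", lineterminator="\n"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.values)


def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities: BC(x,y) = 1 - sum_i min(x_i, y_i)
    for normalized vectors (values in [0, 1]; a semimetric)."""
    if table.mode != "relative":
        raise ValueError("bray_curtis_matrix requires relative mode")
    d = squareform(pdist(table.data.values, metric="braycurtis"))
    return DistanceMatrix(table.samples, d)


@dataclass(frozen=True)
class GroupTestResult:
    scope: str  # "global" or "a|b" pair
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    n_permutations: int | None = None


def pairwise_group_test(values: pd.Series, meta: pd.Series) -> list[GroupTestResult]:
    """Global Kruskal–Wallis plus all pairwise tests, BH-adjusted.

    ``values`` holds one number per sample (e.g. Shannon indices); ``meta``
    maps sample id to group. The first result is the global test; pairwise
    results carry Benjamini–Hochberg adjusted p-values across the pairs.
    """
    groups = meta.reindex(values.index)
    if groups.isna().any():
        raise ValueError("samples without metadata in pairwise_group_test")
    by = {g: values[groups == g].values for g in sorted(groups.unique())}
    if len(by) < 2:
        raise ValueError("need >= 2 groups")
    small = [g for g, v in by.items() if len(v) < 2]
    if small:
        raise ValueError(f"group(s) with < 2 samples: {small}")

    pooled = np.concatenate(list(by.values()))
    if np.ptp(pooled) == 0:  # all identical -> no evidence of difference
        results = [GroupTestResult("global", 0.0, 1.0)]
        names = list(by)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        results += [GroupTestResult(f"{a}|{b}", 0.0, 1.0, 1.0) for a, b in pairs]
        return results

    stat, p = kruskal(*by.values())
    results = [GroupTestResult("global", float(stat), float(p))]
    names = list(by)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = []
    for a, b in pairs:
        if np.ptp(np.concatenate([by[a], by[b]])) == 0:
            raw.append((0.0, 1.0))
        else:
            s, pv = kruskal(by[a], by[b])
            raw.append((float(s), float(pv)))
    adj = multipletests([p for _, p in raw], method="fdr_bh")[1]
    for (a, b), (s, pv), ap in zip(pairs, raw, adj):
        results.append(GroupTestResult(f"{a}|{b}", s, pv, float(ap)))
    return results


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    d: DistanceMatrix,
    meta: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F statistic compares among-group to within-group sums of
    squared distances; significance comes from ``n_perm`` free permutations
    of the sample labels, with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm),
    so the smallest attainable p is 1/(1+n_perm). Seeded and reproducible.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    groups = meta.reindex(d.ids)
    if groups.isna().any():
        raise ValueError("samples without metadata in permanova")
    cats = pd.Categorical(groups)
    n_groups = len(cats.categories)
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    sizes = pd.Series(cats.codes).value_counts()
    if (sizes < 2).any():
        raise ValueError("singleton group in permanova")
    codes = np.asarray(cats.codes)
    d2 = d.values**2
    f_obs = _pseudo_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, n_groups) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return GroupTestResult("global", float(f_obs), float(p), n_permutations=n_perm)
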