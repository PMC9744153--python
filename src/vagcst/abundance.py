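"""Taxa-by-sample abundance tables: I/O, normalization, rarefaction, summaries.

The central container is :class:`AbundanceTable`, a thin wrapper around a
pandas DataFrame (samples as rows, canonical taxa as columns) carrying a
``mode`` flag: ``counts`` (non-negative integers from the sequencer) or
``relative`` (each row a composition summing to 1). Relative abundance (RA)
is the universal unit downstream; the table-reading path canonicalizes taxon
labels through a :class:`~vagcst.registry.TaxonRegistry` and sums columns
that collapse onto the same canonical name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .registry import TaxonRegistry

__all__ = [
    "AbundanceTable",
    "Composition",
    "read_abundance_table",
    "read_biom_json",
    "read_metadata",
    "to_relative_abundance",
    "rarefy_counts",
    "group_mean_profile",
    "panel_total",
]

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """One sample's relative-abundance vector over canonical taxa (sums to 1)."""

    sample_id: str
    ra: Mapping[str, float]

    def __post_init__(self):
        vals = np.asarray(list(self.ra.values()), dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty composition for sample {self.sample_id!r}")
        if (vals < 0).any():
            raise ValueError(f"negative relative abundance in sample {self.sample_id!r}")
        total = vals.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"composition of sample {self.sample_id!r} sums to {total:.6g}, not 1"
            )

    def items(self):
        return self.ra.items()

    def __getitem__(self, taxon: str) -> float:
        return self.ra.get(taxon, 0.0)


@dataclass
class AbundanceTable:
    """Samples × taxa abundance matrix with an explicit unit mode."""

    data: pd.DataFrame  # index: sample ids, columns: canonical taxa
    mode: Literal["counts", "relative"]

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate taxa")
        if (self.data.values < 0).any():
            raise ValueError("negative abundance values")
        if self.mode == "relative":
            sums = self.data.sum(axis=1)
            bad = sums[(sums - 1.0).abs() > 1e-6]
            if len(bad):
                raise ValueError(
                    f"relative-mode rows must sum to 1; offending samples: "
                    f"{list(bad.index[:5])}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def composition(self, sample_id: str) -> Composition:
        if self.mode != "relative":
            raise ValueError("compositions require relative mode; normalize first")
        row = self.data.loc[sample_id]
        return Composition(sample_id, {t: float(v) for t, v in row.items() if v > 0})

    def compositions(self) -> list[Composition]:
        return [self.composition(s) for s in self.samples]

    def to_tsv(self, path: str | Path, orientation: str = "samples_as_rows") -> None:
        df = self.data if orientation == "samples_as_rows" else self.data.T
        label = "sample_id" if orientation == "samples_as_rows" else "taxon"
        df.to_csv(path, sep="\t", index_label=label, lineterminator="\n")

    @staticmethod
    def from_compositions(comps: Iterable[Composition]) -> "AbundanceTable":
        rows = {c.sample_id: dict(c.ra) for c in comps}
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
        df.index.name = "sample_id"
        return AbundanceTable(df, mode="relative")


def _canonicalize_columns(df: pd.DataFrame, registry: TaxonRegistry) -> pd.DataFrame:
    mapping = {col: registry.canonicalize(str(col)).canonical for col in df.columns}
    out = df.rename(columns=mapping)
    if out.columns.has_duplicates:
        out = out.T.groupby(level=0, sort=False).sum().T
    return out


def read_abundance_table(
    path: str | Path,
    registry: TaxonRegistry,
    orientation: Literal["samples_as_rows", "taxa_as_rows"] = "samples_as_rows",
) -> AbundanceTable:
    """Read a tab-separated taxa table, canonicalizing labels via ``registry``.

    Columns whose labels collapse onto the same canonical taxon are summed.
    Mode is auto-detected: rows all summing to ~1 or ~100 are treated as
    relative abundances (percent tables are divided by 100), anything else
    as raw counts. An "Unassigned" column is kept as an ordinary taxon.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_as_rows":
        df = df.T
    df = df.astype(float)
    df.index.name = "sample_id"
    df.columns.name = None
    if (df.values < 0).any():
        raise ValueError(f"negative values in abundance table {path}")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    df = _canonicalize_columns(df, registry)
    sums = df.sum(axis=1)
    if np.allclose(sums, 1.0, atol=1e-6):
        return AbundanceTable(df, mode="relative")
    if np.allclose(sums, 100.0, atol=1e-4):
        return AbundanceTable(df / 100.0, mode="relative")
    return AbundanceTable(df, mode="counts")


def read_biom_json(path: str | Path, registry: TaxonRegistry) -> AbundanceTable:
    """Read a BIOM v1 (JSON) table, read-only; dense or sparse matrices."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)  # BIOM rows are taxa
    df = _canonicalize_columns(df, registry)
    sums = df.sum(axis=1)
    mode = "relative" if np.allclose(sums, 1.0, atol=1e-6) else "counts"
    return AbundanceTable(df, mode=mode)


def read_metadata(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("metadata needs columns: sample_id, group")
    s = df.set_index(df.columns[0])[df.columns[1]]
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    s.name = "group"
    return s


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample's counts by its total; mode becomes ``relative``."""
    if table.mode != "counts":
        raise ValueError("table already in relative mode")
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return AbundanceTable(table.data.div(sums, axis=0), mode="relative")


def rarefy_counts(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Implements multivariate-hypergeometric rarefaction (the standard
    even-depth resampling applied before diversity analyses; the bundled
    survey used depth 80,000). Samples with fewer than ``depth`` total
    reads are dropped with a warning. Deterministic given ``seed``.
    """
    if table.mode != "counts":
        raise ValueError("rarefaction requires counts mode")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.data.round().astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.samples if s not in set(keep)]
    if dropped:
        logger.warning("dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    if not len(keep):
        raise ValueError(f"all samples below rarefaction depth {depth}")
    out = {}
    for s in keep:
        out[s] = rng.multivariate_hypergeometric(counts.loc[s].values, depth)
    df = pd.DataFrame.from_dict(out, orient="index", columns=table.taxa).astype(float)
    df.index.name = table.data.index.name
    return AbundanceTable(df, mode="counts")


def group_mean_profile(
    table: AbundanceTable,
    meta: pd.Series,
    overall: Literal["mean_of_groups", "pooled"] = "mean_of_groups",
) -> tuple[dict[str, Composition], Composition]:
    """Per-group mean RA profiles plus an "overall" profile.

    The per-group profile is the arithmetic mean of its member samples' RA
    vectors. ``overall="mean_of_groups"`` (default) averages the group
    profiles with equal weight regardless of group size — the convention
    under which the bundled survey's overall column is the mean of its five
    cohort columns; ``"pooled"`` averages all samples directly.
    """
    if table.mode != "relative":
        raise ValueError("group_mean_profile requires relative mode")
    missing = [s for s in table.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    groups: dict[str, Composition] = {}
    profiles = []
    for g, idx in table.data.groupby(meta.loc[table.samples]).groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {g!r}")
        prof = table.data.loc[idx].mean(axis=0)
        profiles.append(prof)
        groups[str(g)] = Composition(str(g), {t: float(v) for t, v in prof.items() if v > 0})
    if overall == "mean_of_groups":
        ov = pd.concat(profiles, axis=1).mean(axis=1)
    else:
        ov = table.data.mean(axis=0)
    overall_comp = Composition("overall", {t: float(v) for t, v in ov.items() if v > 0})
    return groups, overall_comp


def panel_total(profile: Composition | Mapping[str, float], panel: Iterable[str]) -> float:
    """Sum of a profile's abundances over a taxon panel (absent members = 0).

    Units follow the profile: fractions in [0, 1] for a normalized
    :class:`Composition`, percent if a percent-scale mapping is passed.
    """
    get = profile.ra.get if isinstance(profile, Composition) else profile.get  # type: ignore[union-attr]
    return float(sum(get(t, 0.0) for t in set(panel)))
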