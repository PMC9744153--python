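"""Rule-based extended community state type (CST) assignment and clustering.

The extended scheme partitions vaginal communities into:

* CST I / II / III / V — dominated (RA >= 50%) by *L. crispatus*,
  *L. gasseri*, *L. iners* or *L. jensenii* respectively;
* CST VI — *G. vaginalis* dominant; CST VII — *Prevotella* dominant;
  CST VIII — a THPP genus dominant (an aerobic-vaginitis-like state);
  CST IX — any other taxon dominant;
* CST IV-A / IV-B / IV-C — polymicrobial states (no taxon at >= 50%) whose
  *most abundant* taxon is *G. vaginalis*, a *Prevotella* bin, or anything
  else, respectively.

Dominance is tested at the registry's working rank: *Lactobacillus* at
species level (otherwise CST I could not be told from CST III), all other
genera at genus level. The 50% threshold is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .abundance import AbundanceTable, Composition
from .registry import CANONICAL_LACTOBACILLI, TaxonGroup, TaxonRegistry

__all__ = [
    "CST_LABELS",
    "ClassifierConfig",
    "CSTAssignment",
    "assign_cst",
    "classify_cohort",
    "summarize_cst_counts",
    "cluster_compositions",
    "ClusteringResult",
]

CST_LABELS = (
    "I", "II", "III", "IV-A", "IV-B", "IV-C", "V", "VI", "VII", "VIII", "IX",
    "UNRESOLVED",
)

_LACTO_CST = {
    "Lactobacillus crispatus": "I",
    "Lactobacillus gasseri": "II",
    "Lactobacillus iners": "III",
    "Lactobacillus jensenii": "V",
}

#: tie-break priority between equally abundant top taxa
_GROUP_PRIORITY = {
    TaxonGroup.LACTOBACILLUS: 0,
    TaxonGroup.GARDNERELLA: 1,
    TaxonGroup.PREVOTELLA: 2,
    TaxonGroup.THPP: 3,
    TaxonGroup.OTHER: 4,
}


@dataclass(frozen=True)
class ClassifierConfig:
    dominance_threshold: float = 0.50  # inclusive >=
    tie_break: tuple[TaxonGroup, ...] = (
        TaxonGroup.LACTOBACILLUS,
        TaxonGroup.GARDNERELLA,
        TaxonGroup.PREVOTELLA,
        TaxonGroup.THPP,
        TaxonGroup.OTHER,
    )
    fold_unresolved_into: str | None = None

    def __post_init__(self):
        if not 0 < self.dominance_threshold <= 1:
            raise ValueError("dominance_threshold must be in (0, 1]")


@dataclass(frozen=True)
class CSTAssignment:
    sample_id: str
    label: str
    dominant_taxon: str
    dominant_ra: float
    rationale: str


def _top_taxon(c: Composition, registry: TaxonRegistry, cfg: ClassifierConfig):
    """Argmax taxon; exact ties broken by group priority then name."""
    rmax = max(c.ra.values())
    tied = sorted(t for t, v in c.ra.items() if v == rmax)
    if len(tied) == 1:
        return tied[0], rmax, False
    prio = {g: i for i, g in enumerate(cfg.tie_break)}
    top = min(tied, key=lambda t: (prio[registry.group_of(t)], t))
    return top, rmax, True


def assign_cst(
    c: Composition, registry: TaxonRegistry, cfg: ClassifierConfig | None = None
) -> CSTAssignment:
    """Assign one extended CST label to a normalized composition.

    The dominance branch fires when the most abundant taxon reaches the
    threshold (inclusive); otherwise the sample is polymicrobial and falls
    into a CST IV subtype keyed on that same most abundant taxon. A
    dominant *Lactobacillus* species outside the canonical four yields
    ``UNRESOLVED`` unless ``cfg.fold_unresolved_into`` redirects it.
    """
    cfg = cfg or ClassifierConfig()
    if not c.ra:
        raise ValueError("empty composition")
    top, r, tied = _top_taxon(c, registry, cfg)
    group = registry.group_of(top)
    tie_note = "; tie broken by group priority" if tied else ""

    if r >= cfg.dominance_threshold:
        if top in _LACTO_CST:
            label = _LACTO_CST[top]
            why = f"dominant {top} ({r:.1%})"
        elif group is TaxonGroup.LACTOBACILLUS:
            label = cfg.fold_unresolved_into or "UNRESOLVED"
            why = f"dominant non-canonical Lactobacillus {top} ({r:.1%})"
        elif group is TaxonGroup.GARDNERELLA:
            label, why = "VI", f"dominant G. vaginalis ({r:.1%})"
        elif group is TaxonGroup.PREVOTELLA:
            label, why = "VII", f"dominant Prevotella ({top}, {r:.1%})"
        elif group is TaxonGroup.THPP:
            label, why = "VIII", f"dominant THPP ({top}, {r:.1%})"
        else:
            label, why = "IX", f"dominant non-panel taxon ({top}, {r:.1%})"
    else:
        if group is TaxonGroup.GARDNERELLA:
            label, why = "IV-A", f"polymicrobial, top G. vaginalis ({r:.1%})"
        elif group is TaxonGroup.PREVOTELLA:
            label, why = "IV-B", f"polymicrobial, top Prevotella ({top}, {r:.1%})"
        else:
            label, why = "IV-C", f"polymicrobial, top {top} ({r:.1%})"
    return CSTAssignment(c.sample_id, label, top, float(r), why + tie_note)


def classify_cohort(
    table: AbundanceTable,
    meta: pd.Series | None = None,
    registry: TaxonRegistry | None = None,
    cfg: ClassifierConfig | None = None,
) -> list[CSTAssignment]:
    """One deterministic assignment per sample of a relative-mode table."""
    if table.mode != "relative":
        raise ValueError("classification requires relative mode")
    registry = registry or _default_registry()
    out = []
    for c in table.compositions():
        try:
            out.append(assign_cst(c, registry, cfg))
        except ValueError as e:
            raise ValueError(f"sample {c.sample_id!r}: {e}") from e
    return out


def _default_registry() -> TaxonRegistry:
    from .registry import default_registry

    return default_registry()


def assignments_frame(assignments: Iterable[CSTAssignment], meta: pd.Series | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "cst": a.label,
                "dominant_taxon": a.dominant_taxon,
                "dominant_ra": a.dominant_ra,
                "rationale": a.rationale,
            }
            for a in assignments
        ]
    )
    if meta is not None and len(df):
        df.insert(1, "group", meta.reindex(df["sample_id"]).values)
    return df


def summarize_cst_counts(
    assignments: Sequence[CSTAssignment], meta: pd.Series | None = None
) -> pd.DataFrame:
    """Counts and percentages per CST, per group and overall.

    Returns a frame indexed by CST label with ``<group>_n``/``<group>_pct``
    columns plus ``overall_n``/``overall_pct``; counts conserve N.
    """
    df = assignments_frame(assignments, meta)
    labels = [l for l in CST_LABELS if len(df) and l in set(df["cst"])]
    out = pd.DataFrame(index=labels)
    if meta is not None and len(df):
        for g, sub in df.groupby("group"):
            n = len(sub)
            counts = sub["cst"].value_counts()
            out[f"{g}_n"] = counts.reindex(labels).fillna(0).astype(int)
            out[f"{g}_pct"] = 100.0 * out[f"{g}_n"] / n
    n_total = len(df)
    counts = df["cst"].value_counts() if n_total else pd.Series(dtype=int)
    out["overall_n"] = counts.reindex(labels).fillna(0).astype(int)
    out["overall_pct"] = 100.0 * out["overall_n"] / n_total if n_total else 0.0
    return out


# ---------------------------------------------------------------------------
# de-novo clustering


@dataclass
class ClusteringResult:
    sample_ids: list[str]
    labels: np.ndarray  # integer cluster ids, 1-based
    linkage: np.ndarray  # scipy linkage matrix (complete agglomeration)
    cluster_to_cst: dict[int, str] = field(default_factory=dict)

    def newick(self) -> str:
        """Serialize the merge tree as a Newick string with merge heights."""
        tree = sch.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id].replace(" ", "_")
            left, right = walk(node.get_left()), walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def cluster_compositions(
    table: AbundanceTable,
    distance: Literal["bray_curtis", "euclidean"] = "bray_curtis",
    k: int | None = None,
    cut_height: float | None = None,
    registry: TaxonRegistry | None = None,
    cfg: ClassifierConfig | None = None,
) -> ClusteringResult:
    """Complete-linkage agglomerative clustering of samples.

    Clusters on Bray–Curtis (default) or Euclidean distance between RA
    vectors; the tree is cut at ``k`` clusters or at ``cut_height``. Each
    cluster is mapped to a CST by majority vote of its members' rule-based
    labels, so de-novo structure can be read against the extended scheme.
    """
    if table.mode != "relative":
        raise ValueError("clustering requires relative mode")
    n = len(table.samples)
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    metric = "braycurtis" if distance == "bray_curtis" else "euclidean"
    dvec = pdist(table.data.values, metric=metric)
    Z = sch.linkage(dvec, method="complete")
    if k is not None:
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
    elif cut_height is not None:
        labels = sch.fcluster(Z, t=cut_height, criterion="distance")
    else:
        raise ValueError("provide k or cut_height")
    res = ClusteringResult(table.samples, labels, Z)
    assigns = classify_cohort(table, registry=registry, cfg=cfg)
    by_sample = {a.sample_id: a.label for a in assigns}
    for cl in np.unique(labels):
        members = [s for s, l in zip(table.samples, labels) if l == cl]
        votes = pd.Series([by_sample[s] for s in members]).value_counts()
        res.cluster_to_cst[int(cl)] = str(votes.index[0])
    return res
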