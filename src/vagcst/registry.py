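"""Canonical taxon nomenclature for vaginal-microbiome analyses.

The registry fixes the working taxonomic rank used throughout the package:
genus for everything except *Lactobacillus* (split into species, because the
CST scheme distinguishes *L. crispatus* / *L. gasseri* / *L. iners* /
*L. jensenii* communities) and *Gardnerella vaginalis*. Species-level labels
of any other known genus are folded into their genus on canonicalization.

Every canonical name belongs to exactly one functional group:

* ``LACTOBACILLUS`` — lactic-acid producing facultative anaerobes;
* ``GARDNERELLA`` — *G. vaginalis*, the keystone biofilm former of BV;
* ``PREVOTELLA`` — the *Prevotella* genus-level bins;
* ``THPP`` — "taxa with high pathogenic potential" (the pathobiont panel:
  *Streptococcus*, *Staphylococcus*, *Enterococcus*, *Escherichia-Shigella*,
  *Mycoplasma*, *Ureaplasma*, and company);
* ``OTHER`` — the implicit complement (heterogeneous anaerobes etc.).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

__all__ = [
    "TaxonGroup",
    "TaxonRank",
    "TaxonName",
    "TaxonRegistry",
    "default_registry",
    "canonicalize",
    "group_of",
    "CANONICAL_LACTOBACILLI",
]

logger = logging.getLogger(__name__)


class TaxonGroup(str, Enum):
    LACTOBACILLUS = "LACTOBACILLUS"
    GARDNERELLA = "GARDNERELLA"
    PREVOTELLA = "PREVOTELLA"
    THPP = "THPP"
    OTHER = "OTHER"


class TaxonRank(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    GROUP = "group"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxonName:
    raw_label: str
    canonical: str
    rank: TaxonRank


#: The four species on which the classical CST I/II/III/V scheme is built.
CANONICAL_LACTOBACILLI = (
    "Lactobacillus crispatus",
    "Lactobacillus gasseri",
    "Lactobacillus iners",
    "Lactobacillus jensenii",
)

# dashes (incl. en/em) unified, underscores -> spaces, case-insensitive
_DASHES = re.compile(r"[‐-―−]")
_WS = re.compile(r"[\s_]+")


def _normkey(label: str) -> str:
    s = _DASHES.sub("-", label.strip())
    s = _WS.sub(" ", s)
    return s.casefold()


@dataclass
class TaxonRegistry:
    """Canonical names, ranks, group memberships and synonym table."""

    taxa: dict[str, TaxonRank] = field(default_factory=dict)
    groups: dict[str, TaxonGroup] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)  # normkey -> canonical
    _index: dict[str, str] = field(default_factory=dict, repr=False)

    def add(self, canonical: str, rank: TaxonRank, group: TaxonGroup = TaxonGroup.OTHER) -> None:
        if canonical in self.taxa:
            raise ValueError(f"duplicate canonical name: {canonical!r}")
        self.taxa[canonical] = rank
        self.groups[canonical] = group
        self._index[_normkey(canonical)] = canonical

    def add_synonym(self, alias: str, canonical: str) -> None:
        if canonical not in self.taxa:
            raise ValueError(f"synonym target {canonical!r} not in registry")
        self.synonyms[_normkey(alias)] = canonical

    # -- lookups ---------------------------------------------------------

    def canonicalize(self, label: str) -> TaxonName:
        """Resolve ``label`` to its canonical :class:`TaxonName`.

        Matching ignores case, surrounding whitespace, underscore/space and
        dash-variant differences. Species labels of a known genus (other
        than the split ranks) fold into the genus. Unknown labels pass
        through unchanged at rank ``unassigned`` with a logged warning.
        Idempotent: canonicalizing a canonical name returns it unchanged.
        """
        if not label or not label.strip():
            raise ValueError("empty taxon label")
        key = _normkey(label)
        if key in self._index:
            canon = self._index[key]
            return TaxonName(label, canon, self.taxa[canon])
        if key in self.synonyms:
            canon = self.synonyms[key]
            return TaxonName(label, canon, self.taxa[canon])
        # species-level label of a known genus -> fold to genus
        head = key.split(" ", 1)[0]
        if head in self._index:
            canon = self._index[head]
            if self.taxa[canon] is TaxonRank.GENUS:
                return TaxonName(label, canon, TaxonRank.GENUS)
        if head in self.synonyms:
            canon = self.synonyms[head]
            if self.taxa[canon] is TaxonRank.GENUS:
                return TaxonName(label, canon, TaxonRank.GENUS)
        # unresolved Lactobacillus species keep species rank so the
        # classifier can flag dominant non-canonical lactobacilli
        if head == "lactobacillus" and " " in key:
            name = label.strip()
            logger.warning("non-canonical Lactobacillus species: %r", label)
            return TaxonName(label, name, TaxonRank.SPECIES)
        logger.warning("unknown taxon label passed through: %r", label)
        return TaxonName(label, label.strip(), TaxonRank.UNASSIGNED)

    def group_of(self, name: TaxonName | str) -> TaxonGroup:
        """Functional group of a canonicalized name (``OTHER`` if unlisted)."""
        canon = name.canonical if isinstance(name, TaxonName) else name
        if canon in self.groups:
            return self.groups[canon]
        if _normkey(canon).startswith("lactobacillus "):
            return TaxonGroup.LACTOBACILLUS
        return TaxonGroup.OTHER

    def members(self, group: TaxonGroup) -> set[str]:
        return {t for t, g in self.groups.items() if g is group}

    # -- serialization ---------------------------------------------------

    def to_file(self, path: str | Path) -> None:
        """Write the registry as tab-separated plain text.

        Two sections: ``canonical_name<TAB>rank<TAB>group`` rows, then a
        ``[synonyms]`` section of ``alias<TAB>canonical`` rows. Lines
        starting with ``#`` are comments.
        """
        lines = ["# vagcst taxon registry", "# canonical_name\trank\tgroup"]
        for canon in sorted(self.taxa):
            lines.append(f"{canon}\t{self.taxa[canon].value}\t{self.groups[canon].value}")
        lines.append("[synonyms]")
        for alias in sorted(self.synonyms):
            lines.append(f"{alias}\t{self.synonyms[alias]}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "TaxonRegistry":
        reg = cls()
        section = "taxa"
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "[synonyms]":
                section = "synonyms"
                continue
            parts = line.split("\t")
            if section == "taxa":
                if len(parts) != 3:
                    raise ValueError(f"malformed registry row: {raw!r}")
                canon, rank, group = parts
                reg.add(canon, TaxonRank(rank), TaxonGroup(group))
            else:
                if len(parts) != 2:
                    raise ValueError(f"malformed synonym row: {raw!r}")
                reg.add_synonym(parts[0], parts[1])
        return reg


# ---------------------------------------------------------------------------
# default registry content

_GENERA_OTHER = (
    "Sneathia",
    "Megasphaera",
    "Atopobium",
    "Anaerococcus",
    "Candidatus Lachnocurva vaginae",
    "Corynebacterium",
    "Veillonella",
    "Fastidiosipila",
    "Bifidobacterium",
    "Peptoniphilus",
    "Dialister",
    "Porphyromonas",
    "Gemella",
    "Finegoldia",
    "Mobiluncus",
    "Parvimonas",
    "Moryella",
    "Aerococcus",
    "Howardella",
    "Acinetobacter",
    "Fusobacterium",
)

_THPP_GENERA = (
    "Campylobacter",
    "Enterococcus",
    "Haemophilus",
    "Escherichia-Shigella",
    "Mycoplasma",
    "Streptococcus",
    "Staphylococcus",
    "Ureaplasma",
    # classifiable from the main-text descriptions beyond the core eight:
    "Peptostreptococcus",
    "Chlamydia",
    "Neisseria",
)

_SYNONYMS = {
    # BVAB1 has been renamed Candidatus Lachnocurva vaginae
    "Shuttleworthia": "Candidatus Lachnocurva vaginae",
    "Shuttleworthia (BVAB1)": "Candidatus Lachnocurva vaginae",
    "Shuttleworthia (BVBA1)": "Candidatus Lachnocurva vaginae",
    "BVAB1": "Candidatus Lachnocurva vaginae",
    "Lachnocurva vaginae": "Candidatus Lachnocurva vaginae",
    # SILVA merges these enterics into one genus-level bin
    "Escherichia": "Escherichia-Shigella",
    "Shigella": "Escherichia-Shigella",
    # common abbreviated binomials
    "L. crispatus": "Lactobacillus crispatus",
    "L. gasseri": "Lactobacillus gasseri",
    "L. iners": "Lactobacillus iners",
    "L. jensenii": "Lactobacillus jensenii",
    "G. vaginalis": "Gardnerella vaginalis",
    "Gardnerella": "Gardnerella vaginalis",
    "M. hominis": "Mycoplasma",
    "U. parvum": "Ureaplasma",
    "Unassigned bacteria": "Unassigned",
}


def default_registry() -> TaxonRegistry:
    """Registry covering the taxa of the bundled five-cohort survey.

    Contains the four canonical *Lactobacillus* species at species rank,
    *G. vaginalis* at species rank, the *Prevotella* group ("Prevotella",
    "Prevotella 6"), the THPP panel nameable from the survey's main tables,
    and the common heterogeneous vaginal genera. Users needing the full
    THPP panel of a specific study can extend a registry file.
    """
    reg = TaxonRegistry()
    for sp in CANONICAL_LACTOBACILLI:
        reg.add(sp, TaxonRank.SPECIES, TaxonGroup.LACTOBACILLUS)
    reg.add("Gardnerella vaginalis", TaxonRank.SPECIES, TaxonGroup.GARDNERELLA)
    reg.add("Prevotella", TaxonRank.GENUS, TaxonGroup.PREVOTELLA)
    reg.add("Prevotella 6", TaxonRank.GENUS, TaxonGroup.PREVOTELLA)
    for g in _THPP_GENERA:
        reg.add(g, TaxonRank.GENUS, TaxonGroup.THPP)
    for g in _GENERA_OTHER:
        reg.add(g, TaxonRank.GENUS, TaxonGroup.OTHER)
    reg.add("Unassigned", TaxonRank.UNASSIGNED, TaxonGroup.OTHER)
    for alias, canon in _SYNONYMS.items():
        reg.add_synonym(alias, canon)
    return reg


def canonicalize(label: str, registry: TaxonRegistry) -> TaxonName:
    """Module-level convenience wrapper for :meth:`TaxonRegistry.canonicalize`."""
    return registry.canonicalize(label)


def group_of(name: TaxonName | str, registry: TaxonRegistry) -> TaxonGroup:
    """Module-level convenience wrapper for :meth:`TaxonRegistry.group_of`."""
    return registry.group_of(name)
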