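"""Agreement between sequence-based and structure-based annotation.

Both annotation routes are summarized as orthology profiles (orthologous
group memberships at named clades, PFAM domain sets, preferred names).
A pair of profiles for the same protein is classified into one of four
mutually exclusive categories:

``ortholog``
    the two annotations share an orthologous group at a narrow clade
    (default: Metazoa, taxid 33208) — the annotations point at orthologs;
``protein_family``
    they share a group only at a broad clade (default: Eukaryota 2759 or
    root 1) — same gene family, orthology unresolved;
``pfam_majority``
    no shared group, but at least half of the *sequence* annotation's
    PFAM domains recur in the structure annotation;
``no_agreement``
    none of the above — the two routes point at non-homologous proteins.

The module also implements the taxon-exclusion self-annotation benchmark:
hits to the query's own taxonomic unit (e.g. its phylum) are discarded and
the surviving top morpholog is checked for shared family-level orthology.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .hits import AnnotationRecord, StructureHit

#: Clades at which a shared orthologous group counts as orthology (narrow)
#: versus same-gene-family (broad).
DEFAULT_ORTHOLOG_TAXIDS = frozenset({33208})  # Metazoa
DEFAULT_FAMILY_TAXIDS = frozenset({1, 2759})  # root, Eukaryota

CATEGORIES = ("ortholog", "protein_family", "pfam_majority", "no_agreement")


class EmapperFormatError(ValueError):
    """Malformed orthology annotation table."""


@dataclass(frozen=True)
class OrthologyProfile:
    """A protein's orthology-derived annotation summary."""

    protein_id: str
    og_memberships: frozenset[tuple[str, int, str]] = frozenset()
    pfam_domains: frozenset[str] = frozenset()
    preferred_name: Optional[str] = None
    description: Optional[str] = None
    go_terms: frozenset[str] = frozenset()
    ec_numbers: frozenset[str] = frozenset()

    def ogs_at(self, taxids: frozenset[int] | set[int]) -> set[str]:
        return {og for og, taxid, _ in self.og_memberships if taxid in taxids}

    def to_annotation_record(self, source: str = "sequence") -> AnnotationRecord:
        return AnnotationRecord(
            protein_id=self.protein_id,
            preferred_name=self.preferred_name,
            description=self.description,
            go_terms=self.go_terms,
            ec_numbers=self.ec_numbers,
            pfam_domains=self.pfam_domains,
            og_memberships=self.og_memberships,
            source=source,
        )


@dataclass(frozen=True)
class AgreementVerdict:
    category: str
    same_preferred_name: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class TaxonGrouping:
    """Maps each species to the taxonomic unit excluded in the benchmark."""

    groups: Mapping[str, str] = field(default_factory=dict)

    def group_of(self, species_id: str) -> str:
        return self.groups[species_id]


def _split_og_token(token: str) -> tuple[str, int, str]:
    # "COG0515@1|root" -> ("COG0515", 1, "root")
    if "@" not in token or "|" not in token:
        raise EmapperFormatError(f"malformed orthologous-group token {token!r}")
    og_id, rest = token.split("@", 1)
    taxid_text, clade_name = rest.split("|", 1)
    try:
        taxid = int(taxid_text)
    except ValueError as exc:
        raise EmapperFormatError(
            f"malformed orthologous-group token {token!r}: bad taxid"
        ) from exc
    return og_id, taxid, clade_name


def _split_field(text: str, sep: str = ",") -> frozenset[str]:
    if not text or text == "-":
        return frozenset()
    return frozenset(part.strip() for part in text.split(sep) if part.strip())


def parse_emapper_table(path: str | Path) -> dict[str, OrthologyProfile]:
    """Parse an emapper-style ``.annotations`` TSV into orthology profiles.

    Comment lines start with ``#``; the last comment line before the data
    is the header (``#query<TAB>...``).  Recognized columns: query,
    eggNOG_OGs, Preferred_name, Description, GOs, EC, PFAMs; ``-`` means
    empty.  Orthologous-group entries look like ``OG@taxid|CladeName``,
    comma-separated.
    """
    header: Optional[list[str]] = None
    profiles: dict[str, OrthologyProfile] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise EmapperFormatError(f"{path}: data before '#'-prefixed header")
            fields = dict(zip(header, line.split("\t")))
            query = fields.get("query", "")
            if not query:
                raise EmapperFormatError(f"{path}: row without a query id")
            og_text = fields.get("eggNOG_OGs", "-")
            memberships = frozenset(
                _split_og_token(tok.strip())
                for tok in og_text.split(",")
                if tok.strip() and og_text != "-"
            )
            name = fields.get("Preferred_name", "") or ""
            desc = fields.get("Description", "") or ""
            profiles[query] = OrthologyProfile(
                protein_id=query,
                og_memberships=memberships,
                pfam_domains=_split_field(fields.get("PFAMs", "-")),
                preferred_name=None if name in ("", "-") else name,
                description=None if desc in ("", "-") else desc,
                go_terms=_split_field(fields.get("GOs", "-")),
                ec_numbers=_split_field(fields.get("EC", "-")),
            )
    return profiles


def same_preferred_name(
    a: Optional[str], b: Optional[str]
) -> bool:
    """Case-insensitive name equality; empty names never match."""
    return bool(a) and bool(b) and a.casefold() == b.casefold()


def classify_agreement(
    seq_profile: OrthologyProfile,
    morf_profile: OrthologyProfile,
    family_taxids: frozenset[int] | set[int] = DEFAULT_FAMILY_TAXIDS,
    ortholog_taxids: frozenset[int] | set[int] = DEFAULT_ORTHOLOG_TAXIDS,
) -> AgreementVerdict:
    """Classify one protein's sequence-vs-structure annotation agreement.

    The PFAM clause is deliberately asymmetric: its denominator is the
    sequence annotation's (unique) domain set, so swapping the arguments
    can change the verdict.
    """
    if not ortholog_taxids or not family_taxids:
        raise ValueError("taxid sets must be non-empty")
    same_name = same_preferred_name(
        seq_profile.preferred_name, morf_profile.preferred_name
    )
    if seq_profile.ogs_at(ortholog_taxids) & morf_profile.ogs_at(ortholog_taxids):
        category = "ortholog"
    elif seq_profile.ogs_at(family_taxids) & morf_profile.ogs_at(family_taxids):
        category = "protein_family"
    elif seq_profile.pfam_domains and (
        len(seq_profile.pfam_domains & morf_profile.pfam_domains)
        >= 0.5 * len(seq_profile.pfam_domains)
    ):
        category = "pfam_majority"
    else:
        category = "no_agreement"
    return AgreementVerdict(category=category, same_preferred_name=same_name)


def category_fractions(verdicts: Iterable[AgreementVerdict]) -> dict[str, float]:
    counts = Counter(v.category for v in verdicts)
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in CATEGORIES}
    return {c: counts.get(c, 0) / total for c in CATEGORIES}


def taxon_exclusion_filter(
    hits: Sequence[StructureHit],
    target_species: Mapping[str, str],
    grouping: TaxonGrouping,
    query_species: str,
) -> list[StructureHit]:
    """Drop hits whose target lies in the query's own taxonomic unit.

    Mirrors the self-annotation benchmark setup: a metazoan query keeps
    only hits outside its phylum, so near-identical proteins from sibling
    species cannot trivially annotate it.  Order is preserved.
    """
    unknown = sorted(
        {h.target_id for h in hits if h.target_id not in target_species}
    )
    if unknown:
        raise KeyError("targets with unknown species: " + ", ".join(unknown))
    query_group = grouping.group_of(query_species)
    return [
        h
        for h in hits
        if grouping.group_of(target_species[h.target_id]) != query_group
    ]


def benchmark_recovery(
    pairs: Sequence[tuple[OrthologyProfile, OrthologyProfile]],
    family_taxids: frozenset[int] | set[int] = DEFAULT_FAMILY_TAXIDS,
) -> float:
    """Fraction of queries whose surviving top morpholog shares a
    family-level orthologous group with the query's own profile.

    Each pair is (query profile, profile of the top morpholog after taxon
    exclusion).  Only queries whose own profile has at least one group at
    a clade in ``family_taxids`` are eligible ("available homologs").
    """
    eligible = [
        (q, m) for q, m in pairs if q.ogs_at(family_taxids)
    ]
    if not eligible:
        raise ValueError("no eligible queries: every query lacks family-level OGs")
    recovered = sum(
        1 for q, m in eligible if q.ogs_at(family_taxids) & m.ogs_at(family_taxids)
    )
    return recovered / len(eligible)
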