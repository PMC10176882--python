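"""Structure-search hit tables: parsing, best-hit selection and annotation transfer.

The structure searches produce BLAST-style 12-column tabular output
(query, target, fident, alnlen, mismatch, gapopen, qstart, qend, tstart,
tend, evalue, bits).  For every query we keep the hit with the highest
corrected bit score in each database, aggregate the per-database winners
into one table, impose a bit-score cutoff (default e^5, strict ``>``),
and transfer the functional annotation of the surviving best hit — the
query's *morpholog* — to the query itself.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

#: Databases the workflow searches by default.  Any other identifier is
#: accepted and treated symmetrically; this tuple just fixes a display order.
KNOWN_DATABASES = ("afdb", "pdb", "swissprot")

#: Default bit-score cutoff, e^5 ~ 148.413.  Comparison is strict (>): a hit
#: exactly at the threshold does not pass.
DEFAULT_BIT_SCORE_CUTOFF = math.exp(5)


class HitTableError(ValueError):
    """Malformed structure-search hit table."""


@dataclass(frozen=True)
class StructureHit:
    """One row of a structure-search result table.

    Coordinates are 1-based inclusive residue positions, the convention of
    the search tools that emit this format.  ``bit_score`` is the tool's
    database-size-corrected bit score and is used verbatim — no further
    correction is applied here.
    """

    query_id: str
    target_id: str
    database: str
    seq_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.seq_identity <= 1.0):
            raise ValueError(f"seq_identity {self.seq_identity} outside [0, 1]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise ValueError("mismatches/gap_opens must be non-negative")
        if self.q_start > self.q_end or self.t_start > self.t_end:
            raise ValueError("alignment coordinates must satisfy start <= end")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass(frozen=True)
class TransferConfig:
    """Parameters of the aggregate-and-filter step."""

    bit_score_cutoff: float = DEFAULT_BIT_SCORE_CUTOFF
    databases: tuple[str, ...] = KNOWN_DATABASES
    tie_break: str = "evalue_then_target_id"

    def __post_init__(self) -> None:
        if self.bit_score_cutoff <= 0:
            raise ValueError("bit_score_cutoff must be positive")
        if not self.databases:
            raise ValueError("databases must be non-empty")
        if self.tie_break != "evalue_then_target_id":
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional descriptors attached to one protein.

    ``source`` records whether the descriptors come from a legacy
    annotation, a direct sequence-based annotation of the protein, or a
    structure-based transfer from its morpholog.
    """

    protein_id: str
    preferred_name: Optional[str] = None
    description: Optional[str] = None
    go_terms: frozenset[str] = frozenset()
    ec_numbers: frozenset[str] = frozenset()
    pfam_domains: frozenset[str] = frozenset()
    og_memberships: frozenset[tuple[str, int, str]] = frozenset()
    source: str = "sequence"

    _SOURCES = ("legacy", "sequence", "structure")

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.source not in self._SOURCES:
            raise ValueError(f"source must be one of {self._SOURCES}")


@dataclass(frozen=True)
class MorphologAssignment:
    """Per-query best morpholog across databases plus transfer status."""

    query_id: str
    best_hit_per_db: Mapping[str, StructureHit] = field(default_factory=dict)
    overall_best: Optional[StructureHit] = None
    passes_cutoff: bool = False
    transferred: Optional[AnnotationRecord] = None


def _hit_rank(hit: StructureHit) -> tuple:
    # max bit score first; ties by smaller e-value, then lexicographically
    # smaller target id, so selection is deterministic.
    return (-hit.bit_score, hit.e_value, hit.target_id)


def read_foldseek_hits(path: str | Path, database: str) -> list[StructureHit]:
    """Read a 12-column tabular hit file into :class:`StructureHit` rows.

    Extra trailing columns are ignored; input order is preserved.  A line
    with fewer than 12 columns or a malformed numeric field raises
    :class:`HitTableError` naming the 1-based line number.
    """
    hits: list[StructureHit] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise HitTableError(
                    f"{path}: line {lineno}: expected >=12 tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hit = StructureHit(
                    query_id=fields[0],
                    target_id=fields[1],
                    database=database,
                    seq_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    t_start=int(fields[8]),
                    t_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise HitTableError(
                    f"{path}: line {lineno}: cannot parse hit row: {exc}"
                ) from exc
            hits.append(hit)
    return hits


def select_best_per_db(
    hits: Iterable[StructureHit],
) -> dict[tuple[str, str], StructureHit]:
    """Best hit (highest bit score) for every (query, database) pair.

    Ties are broken by smaller e-value, then lexicographically smaller
    target id, so the result does not depend on input order.
    """
    best: dict[tuple[str, str], StructureHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.database)
        incumbent = best.get(key)
        if incumbent is None or _hit_rank(hit) < _hit_rank(incumbent):
            best[key] = hit
    return best


def aggregate_and_filter(
    best: Mapping[tuple[str, str], StructureHit],
    cfg: TransferConfig = TransferConfig(),
) -> list[MorphologAssignment]:
    """Aggregate per-database winners into one assignment per query.

    ``overall_best`` is the maximum-bit-score hit across databases (same
    tie-break as :func:`select_best_per_db`); ``passes_cutoff`` is True
    iff its bit score strictly exceeds ``cfg.bit_score_cutoff``.
    """
    per_query: dict[str, dict[str, StructureHit]] = {}
    for (query_id, database), hit in best.items():
        per_query.setdefault(query_id, {})[database] = hit

    assignments = []
    for query_id in sorted(per_query):
        db_hits = per_query[query_id]
        overall = min(db_hits.values(), key=_hit_rank) if db_hits else None
        passes = overall is not None and overall.bit_score > cfg.bit_score_cutoff
        assignments.append(
            MorphologAssignment(
                query_id=query_id,
                best_hit_per_db=dict(db_hits),
                overall_best=overall,
                passes_cutoff=passes,
            )
        )
    return assignments


def transfer_annotations(
    assignments: Iterable[MorphologAssignment],
    target_annotations: Mapping[str, AnnotationRecord],
) -> list[MorphologAssignment]:
    """Copy each passing query's morpholog annotation onto the query.

    The transferred record keeps the morpholog's descriptors but takes the
    query's id and ``source="structure"``.  Queries failing the cutoff, or
    whose morpholog has no annotation on file, end up with
    ``transferred=None`` (the latter with a logged warning).
    """
    out = []
    for asg in assignments:
        transferred = None
        if asg.passes_cutoff and asg.overall_best is not None:
            record = target_annotations.get(asg.overall_best.target_id)
            if record is None:
                logger.warning(
                    "query %s: best hit %s has no annotation on file; "
                    "nothing transferred",
                    asg.query_id,
                    asg.overall_best.target_id,
                )
            else:
                transferred = replace(
                    record, protein_id=asg.query_id, source="structure"
                )
        out.append(replace(asg, transferred=transferred))
    return out


def collapse_to_genes(
    assignments: Iterable[MorphologAssignment],
    isoform_to_gene: Mapping[str, str],
) -> dict[str, MorphologAssignment]:
    """Merge isoform assignments, keeping per gene the best-bit-score entry.

    Hit-less isoforms rank below any isoform with a hit; genes whose
    isoforms all lack hits keep a hit-less record.  Every isoform must be
    present in the map.
    """
    assignments = list(assignments)
    missing = [a.query_id for a in assignments if a.query_id not in isoform_to_gene]
    if missing:
        raise KeyError(
            "isoforms missing from isoform_to_gene map: " + ", ".join(sorted(missing))
        )

    def rank(asg: MorphologAssignment) -> tuple:
        if asg.overall_best is None:
            return (1, (), asg.query_id)
        return (0, _hit_rank(asg.overall_best), asg.query_id)

    by_gene: dict[str, MorphologAssignment] = {}
    for asg in assignments:
        gene = isoform_to_gene[asg.query_id]
        incumbent = by_gene.get(gene)
        if incumbent is None or rank(asg) < rank(incumbent):
            by_gene[gene] = asg
    return by_gene


#: Slots checked, in priority order, by :func:`compose_display_name`.
_NAME_SLOTS = (
    ("legacy", "preferred_name", "legacy"),
    ("legacy", "description", "legacy"),
    ("seq", "preferred_name", "seq_name"),
    ("seq", "description", "seq_description"),
    ("morf", "preferred_name", "morf_name"),
    ("morf", "description", "morf_description"),
)


def compose_display_name(
    legacy: Optional[AnnotationRecord],
    seq: Optional[AnnotationRecord],
    morf: Optional[AnnotationRecord],
) -> tuple[str, str]:
    """Pick a display name, preferring sequence-derived annotation.

    Priority: legacy name/description, then the sequence annotation's
    preferred name, then its description, then the structure-transferred
    (morpholog) name and description.  Returns ``(name, provenance)``;
    all-empty input yields ``("unannotated", "none")``.
    """
    records = {"legacy": legacy, "seq": seq, "morf": morf}
    for which, attr, provenance in _NAME_SLOTS:
        record = records[which]
        if record is None:
            continue
        value = getattr(record, attr)
        if value:
            return value, provenance
    return "unannotated", "none"


# ---------------------------------------------------------------------------
# assignment table I/O

ASSIGNMENT_COLUMNS = (
    "query_id",
    "gene_id",
    "best_db",
    "target_id",
    "bit_score",
    "e_value",
    "passes_cutoff",
    "preferred_name",
    "description",
    "provenance",
)


def assignment_row(
    asg: MorphologAssignment, gene_id: Optional[str] = None
) -> dict[str, str]:
    """Flatten an assignment into the output-table row format."""
    best = asg.overall_best
    return {
        "query_id": asg.query_id,
        "gene_id": gene_id or asg.query_id,
        "best_db": best.database if best else "",
        "target_id": best.target_id if best else "",
        "bit_score": repr(best.bit_score) if best else "",
        "e_value": repr(best.e_value) if best else "",
        "passes_cutoff": "true" if asg.passes_cutoff else "false",
        "preferred_name": (asg.transferred.preferred_name or "")
        if asg.transferred
        else "",
        "description": (asg.transferred.description or "") if asg.transferred else "",
        "provenance": "structure" if asg.transferred else "",
    }


def write_assignment_table(
    rows: Sequence[Mapping[str, str]], path: str | Path
) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=ASSIGNMENT_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_assignment_table(path: str | Path) -> list[dict[str, str]]:
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [dict(row) for row in reader]
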