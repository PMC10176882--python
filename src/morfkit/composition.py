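"""Compositional screening of horizontal-gene-transfer candidates.

A gene acquired from a foreign genome tends to carry the donor's
nucleotide composition: its GC content and synonymous codon preferences
deviate from the host transcriptome.  This module summarizes each coding
sequence by GC content, Relative Synonymous Codon Usage (RSCU: observed
codon count over the mean count of its synonymous family) and Wright's
effective number of codons (ENC, 20 = one codon per family, 61 = uniform
usage), fits a transcriptome-wide background, and z-scores candidate
genes against it.  A gene is *compositionally typical* — evidence against
recent foreign origin — when both its GC z-score (two-sided) and its
RSCU-distance z-score stay below the threshold.

Cross-species presence is summarized separately: per candidate gene and
per related species, the best-scoring alignment bit score (a gene found
across many relatives is unlikely to be a contaminant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .hits import read_foldseek_hits

#: Synonymous families of the standard genetic code, excluding Met, Trp
#: (non-degenerate) and stops: 18 amino acids, 59 sense codons.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
SYNONYMOUS_FAMILIES = {
    aa: codons for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) > 1
}
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for codons in SYNONYMOUS_FAMILIES.values() for c in codons
)
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: Guard against zero background dispersion when z-scoring.
SD_FLOOR = 1e-6


class CdsError(ValueError):
    """Coding sequence unusable for codon statistics."""


@dataclass(frozen=True)
class CodonUsageProfile:
    """Per-gene composition summary against no particular background."""

    gene_id: str
    gc_content: float
    rscu: Mapping[str, float]  # only defined coordinates present
    enc: Optional[float]
    n_codons: int
    internal_stop: bool = False


@dataclass(frozen=True)
class CompositionBackground:
    """Transcriptome-wide composition summary used for z-scoring.

    Stores mean and (sample) standard deviation of GC and of every RSCU
    coordinate, plus the distribution of background genes' RSCU distances
    to the background mean.
    """

    n_genes: int
    gc_mean: float
    gc_sd: float
    rscu_mean: Mapping[str, float]
    rscu_sd: Mapping[str, float]
    distance_mean: float
    distance_sd: float


@dataclass(frozen=True)
class HgtReport:
    gene_id: str
    gc_z: float
    codon_distance_z: float
    composition_typical: bool
    species_presence: Mapping[str, float] = field(default_factory=dict)


def gc_content(cds: str) -> float:
    """GC fraction over unambiguous bases (A/C/G/T only, either case)."""
    seq = cds.upper()
    counts = {base: seq.count(base) for base in "ACGT"}
    denominator = sum(counts.values())
    if denominator == 0:
        raise CdsError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denominator


def _codons(cds: str) -> list[str]:
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise CdsError(f"length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]  # trim terminal stop
    return codons


def codon_counts(cds: str) -> tuple[dict[str, int], bool]:
    """Counts of sense codons plus an internal-stop flag."""
    codons = _codons(cds)
    counts: dict[str, int] = {}
    internal_stop = False
    for codon in codons:
        if codon in STOP_CODONS:
            internal_stop = True
            continue
        if codon in _TABLE.forward_table:
            counts[codon] = counts.get(codon, 0) + 1
    if not counts:
        raise CdsError("no sense codons in sequence")
    return counts, internal_stop


def rscu(cds: str, gene_id: str = "?") -> CodonUsageProfile:
    """Relative synonymous codon usage profile of one coding sequence.

    ``RSCU(c) = count(c) / mean count over c's synonymous family``.
    Families never observed in the gene yield no coordinates (they are
    excluded from downstream distances); Met, Trp and stops are excluded
    throughout.
    """
    counts, internal_stop = codon_counts(cds)
    values: dict[str, float] = {}
    for _aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in family)
        if total == 0:
            continue
        mean_count = total / len(family)
        for c in family:
            values[c] = counts.get(c, 0) / mean_count
    return CodonUsageProfile(
        gene_id=gene_id,
        gc_content=gc_content(cds),
        rscu=values,
        enc=enc_from_counts(counts),
        n_codons=sum(counts.values()),
        internal_stop=internal_stop,
    )


def enc_from_counts(counts: Mapping[str, int]) -> Optional[float]:
    """Wright's effective number of codons from sense-codon counts.

    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` where ``Fk`` averages the
    family homozygosity ``F = (n * sum(p^2) - 1) / (n - 1)`` over k-fold
    families with at least 2 observations.  Undefined (None) when any
    degeneracy class has no usable family; clipped to at most 61.
    """
    by_degeneracy: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for _aa, family in SYNONYMOUS_FAMILIES.items():
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        probs = [counts.get(c, 0) / n for c in family]
        f_hat = (n * sum(p * p for p in probs) - 1) / (n - 1)
        by_degeneracy[len(family)].append(f_hat)
    means: dict[int, float] = {}
    for k, values in by_degeneracy.items():
        if not values:
            return None
        mean = sum(values) / len(values)
        if mean <= 0:
            return None
        means[k] = mean
    enc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(enc, 61.0)


def enc(cds: str) -> Optional[float]:
    """ENC of a coding sequence (see :func:`enc_from_counts`)."""
    counts, _ = codon_counts(cds)
    return enc_from_counts(counts)


def _rscu_distance(
    profile_rscu: Mapping[str, float], mean: Mapping[str, float]
) -> float:
    coords = [c for c in profile_rscu if c in mean]
    if not coords:
        return 0.0
    return math.sqrt(sum((profile_rscu[c] - mean[c]) ** 2 for c in coords))


def fit_background(profiles: Sequence[CodonUsageProfile]) -> CompositionBackground:
    """Fit the transcriptome background from >=2 gene profiles."""
    if len(profiles) < 2:
        raise ValueError("background requires at least 2 gene profiles")
    gc = np.array([p.gc_content for p in profiles])
    rscu_mean: dict[str, float] = {}
    rscu_sd: dict[str, float] = {}
    for codon in DEGENERATE_CODONS:
        values = np.array([p.rscu[codon] for p in profiles if codon in p.rscu])
        if values.size >= 2:
            rscu_mean[codon] = float(values.mean())
            rscu_sd[codon] = float(values.std(ddof=1))
    distances = np.array([_rscu_distance(p.rscu, rscu_mean) for p in profiles])
    return CompositionBackground(
        n_genes=len(profiles),
        gc_mean=float(gc.mean()),
        gc_sd=float(gc.std(ddof=1)),
        rscu_mean=rscu_mean,
        rscu_sd=rscu_sd,
        distance_mean=float(distances.mean()),
        distance_sd=float(distances.std(ddof=1)),
    )


def composition_outlier_score(
    profile: CodonUsageProfile,
    background: CompositionBackground,
    z_threshold: float = 3.0,
    sd_floor: float = SD_FLOOR,
) -> HgtReport:
    """Z-score one gene's composition against the background.

    ``gc_z`` is the two-sided GC z-score; ``codon_distance_z`` z-scores
    the gene's Euclidean RSCU distance to the background mean against the
    background genes' own distance distribution.  The gene is typical iff
    ``|gc_z| < z_threshold`` and ``codon_distance_z < z_threshold``.
    """
    gc_z = (profile.gc_content - background.gc_mean) / max(
        background.gc_sd, sd_floor
    )
    distance = _rscu_distance(profile.rscu, background.rscu_mean)
    distance_z = (distance - background.distance_mean) / max(
        background.distance_sd, sd_floor
    )
    return HgtReport(
        gene_id=profile.gene_id,
        gc_z=float(gc_z),
        codon_distance_z=float(distance_z),
        composition_typical=bool(
            abs(gc_z) < z_threshold and distance_z < z_threshold
        ),
    )


def screen_genes(
    profiles: Sequence[CodonUsageProfile],
    candidate_ids: Iterable[str],
    z_threshold: float = 3.0,
) -> list[HgtReport]:
    """Score candidate genes against the rest of the cohort.

    The null background is fitted on the non-candidate profiles: the
    genes under suspicion must not shape the distribution they are
    tested against (with genuinely foreign candidates they would inflate
    its dispersion and mask themselves).  When the candidates are the
    whole cohort, the background falls back to all profiles.
    """
    candidate_ids = list(candidate_ids)
    candidate_set = set(candidate_ids)
    null_profiles = [p for p in profiles if p.gene_id not in candidate_set]
    if len(null_profiles) < 2:
        null_profiles = list(profiles)
    background = fit_background(null_profiles)
    by_id = {p.gene_id: p for p in profiles}
    reports = []
    for gene_id in candidate_ids:
        if gene_id not in by_id:
            raise KeyError(f"candidate {gene_id} absent from the CDS cohort")
        reports.append(
            composition_outlier_score(by_id[gene_id], background, z_threshold)
        )
    return reports


def cross_species_best_hits(
    alignment_tables: Mapping[str, str | Path],
    genes: Sequence[str],
    isoform_to_gene: Optional[Mapping[str, str]] = None,
) -> "pd.DataFrame":
    """Best bit score per (gene, species) from per-species hit tables.

    Each table is a 12-column tabular alignment file; isoform-level
    queries are collapsed to their gene by max bit score.  Absent
    (gene, species) pairs are NaN.  Returns a genes x species DataFrame.
    """
    import pandas as pd

    species_names = sorted(alignment_tables)
    matrix = pd.DataFrame(
        np.nan, index=list(genes), columns=species_names, dtype=float
    )
    for species in species_names:
        path = alignment_tables[species]
        try:
            hits = read_foldseek_hits(path, database=species)
        except (OSError, ValueError) as exc:
            raise ValueError(f"unreadable hit table for species {species}: {exc}")
        for hit in hits:
            gene = (
                isoform_to_gene.get(hit.query_id, hit.query_id)
                if isoform_to_gene
                else hit.query_id
            )
            if gene not in matrix.index:
                continue
            current = matrix.at[gene, species]
            if np.isnan(current) or hit.bit_score > current:
                matrix.at[gene, species] = hit.bit_score
    return matrix
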