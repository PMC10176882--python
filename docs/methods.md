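# Methods

This note documents the conventions, defaults and design choices behind
`morfkit`, and what the synthetic fixtures do and do not establish.

## Morpholog selection and annotation transfer

A structure search of a query proteome against several databases yields
BLAST-style 12-column tabular hits. Per (query, database) the hit with
the highest corrected bit score is kept; the bit score is used verbatim
from the search tool's `bits` column (the database-size correction is
internal to the tool). Per-database winners are aggregated and the
overall best hit across databases becomes the query's morpholog.

**Cutoff.** The default bit-score cutoff is e⁵ ≈ 148.4132, applied
*strictly* (`bit_score > cutoff`): the threshold value itself fails.
The sources describing this filtering do not state whether the boundary
is inclusive; strictness was fixed here as a convention and is encoded
in `TransferConfig`.

**Ties.** Equal bit scores are broken by smaller e-value, then
lexicographically smaller target id. This is a determinism convention,
not an empirical claim; it makes selection independent of input order
(verified by permutation tests).

**Transfer.** A passing query receives a copy of its morpholog's
annotation record (preferred name, description, GO, EC, PFAM, OG
memberships) with `source="structure"`. A passing query whose target
has no annotation on file gets nothing, with a logged warning. Isoform
assignments collapse to genes by best bit score (hit-less isoforms rank
last). Display names prefer sequence-derived annotation: legacy name or
description, then the sequence annotation's preferred name, then its
description, then the structure-transferred name and description;
all-empty yields `"unannotated"`.

## Agreement categories

Agreement between a protein's sequence-derived and structure-derived
annotation is classified against orthologous-group (OG) memberships:

1. **ortholog** — any shared OG at a clade in the *ortholog* taxid set
   (default {33208} Metazoa, matching a metazoan query proteome; the
   operational clade is configurable because "most recent common
   ancestor" depends on the query species);
2. **protein_family** — otherwise, any shared OG at a clade in the
   *family* set (default {1 root, 2759 Eukaryota});
3. **pfam_majority** — otherwise, at least half of the **sequence**
   annotation's unique PFAM accessions recur in the structure
   annotation. The denominator choice (sequence set, not the union) is
   deliberate and makes the clause asymmetric; repeat domains count
   once. The output header records this convention.
4. **no_agreement** — none of the above.

Preferred-name equality is case-insensitive; empty names never match.
The four categories are exhaustive and mutually exclusive (verified
over the full 16-combination truth table).

The taxon-exclusion benchmark removes hits whose target lies in the
query's own taxonomic unit (e.g. its phylum) before taking the top
morpholog, and reports the fraction of eligible queries (those with at
least one family-level OG of their own) whose surviving top morpholog
shares a family-level OG.

## EC agreement

EC codes are 4-field tuples; `-` and preliminary `n`-prefixed fields
are wildcards, and fields after the first wildcard are normalized to
wildcards. Agreement depth is the common specified prefix length (0–4),
symmetric, stopping at the first mismatch or wildcard. Proteins with
several EC numbers are scored by the best cross pair (max), since a
single per-pair agreement must be reported and no aggregation rule is
canonical.

Top-range consistency interprets "the 90th percentile of the score
range" as a *range* fraction — hits with
`bit_score ≥ s_min + q·(s_max − s_min)`, default q = 0.9 — because the
phrase names the range, not the rank distribution. A rank-percentile
mode (`--percentile-mode rank`, `numpy.quantile`) is provided and
labeled in the output, since the reading is genuinely ambiguous.
Single-hit queries, EC-less best hits and EC-less peers are skipped
("not evaluable", `None`), never scored as zero.

## GO semantics

The ontology is restricted to `is_a` and `part_of` edges; obsolete
stanzas are recorded but excluded, alt ids resolve to primary ids, and
a cycle is a hard format error.

Wang S-values over a term's ancestor sub-DAG are max path products of
edge weights (is_a 0.8, part_of 0.6 — the classic Wang constants).
Some downstream tools modify these weights with child counts; their
exact constants are not restated in the sources available here, so the
classic weights are the default and the weight function is pluggable
(any `relation→factor` mapping or `f(child, parent, relation)`
callable) without further code changes. Pair similarity is the summed
S-values over shared ancestors normalized by both SV totals; gene-level
similarity is Average-Best-Match (each term matched to its best
counterpart, averaged over both directions). ABM(A, A) = 1 for any
non-empty A.

Overlap classes (identical / partial / disjoint / not comparable)
compare **raw** annotation sets, without ancestor closure — the direct
set comparison; this is flagged in the output header since closure
would only increase overlap.

Depth is the longest `is_a` path from the namespace root (the
convention of the common GO toolkits); `level` (shortest path) is
exposed alongside. `part_of` edges contribute to similarity sub-DAGs
but never to depth.

## Compositional HGT screen

Candidate genes are screened for foreign nucleotide composition:

- **GC content** over unambiguous bases only;
- **RSCU**: observed codon count over the mean count of its synonymous
  family, over the 59 degenerate sense codons (Met, Trp, stops
  excluded); unobserved families contribute no coordinates;
- **ENC** (Wright): `2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` with
  `F = (nΣp² − 1)/(n − 1)`, families with n < 2 skipped, undefined when
  a degeneracy class is empty, clipped to 61.

The screen z-scores a gene's GC (two-sided) and its Euclidean RSCU
distance to the background mean (against the background genes' own
distance distribution, one-sided); *typical* means both stay below the
threshold (default z = 3, a conventional outlier bound — no numeric
threshold is prescribed by the sources). Background mean/sd use
`ddof=1`; an sd floor of 1e-6 guards degenerate backgrounds. Which
codon-usage statistic drives the screen is not canonical; the RSCU
distance is the default and ENC is reported alongside, with the choice
labeled in the output.

`screen_genes` fits the null background on the **non-candidate**
profiles: the genes under suspicion must not shape the distribution
they are tested against — at desk-scale cohorts (hundreds of genes,
tens of candidates) genuinely foreign candidates would otherwise
inflate the background dispersion and mask themselves, whereas in a
full transcriptome the difference is negligible.

Intron presence and genome-contig co-location, which also bear on HGT
calls, require genome assemblies and are out of scope; the report
schema leaves room for externally supplied evidence columns.

## Structure metrics

Models are reduced to their Cα trace; pLDDT is read from the B-factor
column. Band boundaries (>90 / 70–90 / 50–70 / <50) are assigned
upward-exclusive (a value exactly at a boundary falls in the lower
band), a fixed convention since the canonical intervals are open.

Superposition is least-squares rigid (Kabsch, SVD with determinant
correction so the rotation is always proper) **on an explicitly
supplied pairing**. The sequence-independent structural aligner used to
produce published figure superpositions is not reimplemented, so RMSDs
here are not comparable to figure captions computed with such aligners;
pairings can come from a hit table's aligned ranges.

Long-helix triage uses the ratio of the two largest gyration-tensor
eigenvalues (λ₁/λ₂ of the centered Cα second-moment matrix): ≈1 for
globular clouds, ≫10 for rods; default threshold 10, configurable;
collinear traces return an infinity sentinel. This is far cheaper than
secondary-structure assignment and sufficient for rod detection, which
is all the triage needs. Triage selects proteins with no transferred
annotation and mean pLDDT strictly above 70, splitting no-hit from
below-cutoff cases and helix-like from globular shapes.

Physico-chemical properties: GRAVY is the mean Kyte–Doolittle
hydropathy and the instability index the standard `(10/L)·Σ` dipeptide
weight sum (both weight tables imported from Biopython's published
data, not re-typed). The isoelectric point solves net charge = 0 by
Brent's method on (0, 14) under the EMBOSS pKa set (N-terminus 8.6,
C-terminus 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1);
the charge function is strictly decreasing so the root is unique, and
the residual charge at the returned pI is below 1e-4 by construction.
Residues outside the 20 standard amino acids are skipped; more than 10%
unknowns is an error.

## Synthetic fixtures

All generators draw from `numpy.random.default_rng` (PCG64) seeded from
the `FixtureSpec`, so identical specs give byte-identical files on any
platform, and every generator writes a machine-readable truth file that
downstream tests consume — expectations are never regenerated.

Defaults are the study conditions: 200 queries over three databases
with a planted per-database best above all decoys, an exact 30% of
hit-bearing queries below the e⁵ cutoff and 5% with no hits at all;
1000-protein agreement cohorts with category fractions
(0.567, 0.339, 0.047, 0.047) — the composition reported for a real
sponge-proteome comparison — planted exactly by largest-remainder
apportionment; CDS cohorts of 500 background genes (per-gene GC targets
from Normal(0.45, 0.03), a realistic transcriptome center) plus 10
foreign genes shifted +0.15 in GC, lengths 300–600 codons, codons drawn
from an exponentially GC-tilted model whose tilt is solved per gene by
root finding; and 60–120-residue models written as strict fixed-column
PDB ATOM records, ideal α-helices (rise 1.5 Å, radius 2.3 Å, 100°/res)
or Gaussian globules, with a single per-model pLDDT value at B-factor
precision so the planted mean round-trips exactly.

What the fixtures are *not*: biological sequences. Background genes are
i.i.d. draws from one codon model — no amino-acid composition
constraints, no isochores, no expression-correlated codon bias; decoy
hits have no correlated scores; annotation tables realize categories
minimally. Passing tests therefore demonstrate the algorithms'
correctness against their definitions and planted truth, not
performance on real proteomes, where effect sizes and error rates will
differ.

## Problem sizes and numerics

Test and acceptance runs use desk-scale cohorts chosen to exercise the
claims comfortably: ~10⁴ hit rows for selection oracles, 1000-protein
agreement cohorts, 20 seeded replicates of the 510-gene HGT screen,
random DAGs ≤30 terms for exponential-oracle checks, 6561-pair EC
enumeration, and 10-point sets for the rotation-grid Kabsch oracle.
Headline numbers in the study this mirrors (e.g. proteome-wide
annotation coverage) depend on full structure databases and are not
reproducible at this scale; the package's own quantities are defined to
be recomputable from seeds alone.

Numerical conventions worth knowing: sample (ddof=1) standard
deviations throughout the composition background; strict inequalities
at the bit-score cutoff and the pLDDT triage threshold; upward-exclusive
pLDDT band edges; e-value-then-target-id tie-breaks; and an explicit
infinity sentinel (never an exception) for degenerate elongation
inputs.
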