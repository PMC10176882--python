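"""Seeded synthetic-fixture generators with planted ground truth.

Every generator writes the corresponding on-disk input format (hit
tables, orthology annotation tables, CDS FASTA, OBO ontology, PDB
models) together with a machine-readable truth file, so each downstream
module can be exercised and checked without any external data.  The
fixtures are statistical stand-ins, not biological sequences.

All randomness flows through ``numpy.random.default_rng`` seeded from
``FixtureSpec.seed`` (an integer-state PCG64 generator), so the same
spec produces byte-identical files on any platform.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .agreement import OrthologyProfile
from .composition import SYNONYMOUS_FAMILIES
from .hits import DEFAULT_BIT_SCORE_CUTOFF

#: Fig-1C-style study composition used as the default planted category mix.
DEFAULT_CATEGORY_FRACTIONS = {
    "ortholog": 0.567,
    "protein_family": 0.339,
    "pfam_majority": 0.047,
    "no_agreement": 0.047,
}

_ALL_SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(
        c
        for family in SYNONYMOUS_FAMILIES.values()
        for c in family
    )
) + ("ATG", "TGG")

_AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # hit tables
    n_queries: int = 200
    databases: tuple[str, ...] = ("afdb", "pdb", "swissprot")
    below_cutoff_fraction: float = 0.3
    no_hit_fraction: float = 0.05
    annotated_target_fraction: float = 0.9
    # agreement tables
    n_proteins: int = 1000
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS)
    )
    same_name_fraction: float = 0.7
    # CDS cohort
    n_genes: int = 500
    n_foreign: int = 10
    gc_background: float = 0.45
    gc_sd: float = 0.03
    gc_shift: float = 0.15
    rscu_shift: float = 0.0
    min_codons: int = 300
    max_codons: int = 600
    n_species: int = 8
    species_presence: float = 0.85
    # structure models
    n_models: int = 20
    helix_fraction: float = 0.5
    folded_fraction: float = 0.7
    min_residues: int = 60
    max_residues: int = 120


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # independent, platform-stable stream per generator
    return np.random.default_rng([spec.seed, stream])


def _exact_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so planted fractions are exact."""
    keys = list(fractions)
    raw = {k: n * fractions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    remainder = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_emapper_table(
    profiles: Sequence[OrthologyProfile], path: str | Path
) -> None:
    """Write orthology profiles in the emapper ``.annotations`` dialect."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "#query\teggNOG_OGs\tDescription\tPreferred_name\tGOs\tEC\tPFAMs\n"
        )
        for p in profiles:
            ogs = (
                ",".join(
                    f"{og}@{taxid}|{clade}"
                    for og, taxid, clade in sorted(p.og_memberships)
                )
                or "-"
            )
            fh.write(
                "\t".join(
                    [
                        p.protein_id,
                        ogs,
                        p.description or "-",
                        p.preferred_name or "-",
                        ",".join(sorted(p.go_terms)) or "-",
                        ",".join(sorted(p.ec_numbers)) or "-",
                        ",".join(sorted(p.pfam_domains)) or "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# hit tables


def make_hit_tables(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Hit tables with a planted best hit per (query, database).

    Decoy hits sit strictly below the planted per-database best; an exact
    ``below_cutoff_fraction`` of hit-bearing queries has its overall best
    below e^5, and an exact ``no_hit_fraction`` of queries appears in no
    table at all.  Also emits the morpholog annotation table (a fraction
    of best-hit targets annotated), an isoform-to-gene map (two isoforms
    per gene), and truth tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 1)
    n = spec.n_queries
    queries = [f"q{i:05d}" for i in range(n)]

    n_no_hit = round(spec.no_hit_fraction * n)
    order = rng.permutation(n)
    no_hit = {queries[i] for i in order[:n_no_hit]}
    with_hits = [q for q in queries if q not in no_hit]
    n_below = round(spec.below_cutoff_fraction * len(with_hits))
    below = set(
        np.array(with_hits)[rng.permutation(len(with_hits))[:n_below]]
    )

    rows_per_db: dict[str, list[list]] = {db: [] for db in spec.databases}
    truth_best_rows = []
    truth_overall_rows = []
    annotated_targets: list[OrthologyProfile] = []
    cutoff = DEFAULT_BIT_SCORE_CUTOFF

    def hit_row(query, target, bits, e_value, rng):
        aln = int(rng.integers(80, 400))
        ident = round(float(rng.uniform(0.08, 0.6)), 3)
        return [
            query, target, f"{ident:.3f}", aln,
            int(rng.integers(0, aln)), int(rng.integers(0, 10)),
            1, aln, 1, aln, f"{e_value:.3e}", f"{bits:.1f}",
        ]

    for qi, query in enumerate(queries):
        if query in no_hit:
            truth_overall_rows.append([query, "", "", "", "no_hit"])
            continue
        if query in below:
            overall_bits = round(float(rng.uniform(60, cutoff - 2)), 1)
            status = "below"
        else:
            overall_bits = round(float(rng.uniform(170, 480)), 1)
            status = "pass"
        best_db = spec.databases[int(rng.integers(len(spec.databases)))]
        for db in spec.databases:
            target = f"T{qi:05d}_{db}"
            if db == best_db:
                bits = overall_bits
            else:
                bits = round(float(rng.uniform(50, overall_bits - 5)), 1)
            e_value = 10 ** (-bits / 10)
            rows_per_db[db].append(hit_row(query, target, bits, e_value, rng))
            truth_best_rows.append([query, db, target, f"{bits:.1f}"])
            # decoys strictly below the per-database best
            for d in range(int(rng.integers(1, 4))):
                decoy_bits = round(bits - float(rng.uniform(1.0, 30.0)), 1)
                rows_per_db[db].append(
                    hit_row(
                        query, f"D{qi:05d}_{db}_{d}", decoy_bits,
                        10 ** (-decoy_bits / 10), rng,
                    )
                )
        best_target = f"T{qi:05d}_{best_db}"
        truth_overall_rows.append(
            [query, best_db, best_target, f"{overall_bits:.1f}", status]
        )
        if status == "pass" and rng.random() < spec.annotated_target_fraction:
            annotated_targets.append(
                OrthologyProfile(
                    protein_id=best_target,
                    preferred_name=f"NAME{qi:05d}",
                    description=f"synthetic morpholog protein {qi:05d}",
                    og_memberships=frozenset(
                        {(f"OG{qi:05d}", 33208, "Metazoa")}
                    ),
                    pfam_domains=frozenset({f"PF{qi:05d}"}),
                )
            )

    paths = {}
    for db in spec.databases:
        rows = rows_per_db[db]
        perm = rng.permutation(len(rows))
        path = out / f"hits_{db}.tsv"
        with open(path, "wt", encoding="utf-8") as fh:
            for i in perm:
                fh.write("\t".join(str(x) for x in rows[i]) + "\n")
        paths[db] = path

    annotations_path = out / "morpholog_annotations.tsv"
    write_emapper_table(annotated_targets, annotations_path)
    isoform_map_path = out / "isoform_map.tsv"
    _write_tsv(
        isoform_map_path,
        ["isoform", "gene"],
        [[q, f"g{i // 2:05d}"] for i, q in enumerate(queries)],
    )
    truth_best_path = out / "truth_best_per_db.tsv"
    _write_tsv(
        truth_best_path, ["query", "database", "target", "bit_score"], truth_best_rows
    )
    truth_overall_path = out / "truth_overall.tsv"
    _write_tsv(
        truth_overall_path,
        ["query", "best_db", "target", "bit_score", "status"],
        truth_overall_rows,
    )
    return {
        "hit_tables": paths,
        "annotations": annotations_path,
        "isoform_map": isoform_map_path,
        "truth_best_per_db": truth_best_path,
        "truth_overall": truth_overall_path,
    }


# ---------------------------------------------------------------------------
# agreement tables


def make_annotation_tables(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Paired sequence/structure annotation tables with planted categories.

    Category counts follow ``spec.category_fractions`` exactly (largest
    remainder); an exact ``same_name_fraction`` of proteins carries the
    same preferred name in both tables (with differing case, to exercise
    case folding).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 2)
    n = spec.n_proteins
    counts = _exact_counts(n, dict(spec.category_fractions))
    categories = [c for c in counts for _ in range(counts[c])]
    categories = [categories[i] for i in rng.permutation(n)]
    n_same = round(spec.same_name_fraction * n)
    same_name_flags = np.zeros(n, dtype=bool)
    same_name_flags[rng.permutation(n)[:n_same]] = True

    seq_profiles, morf_profiles, truth_rows = [], [], []
    for i in range(n):
        protein = f"p{i:05d}"
        category = categories[i]
        same = bool(same_name_flags[i])
        seq_name = f"Gene{i:05d}"
        morf_name = seq_name.upper() if same else f"Other{i:05d}"
        seq_ogs, morf_ogs = set(), set()
        seq_pfams, morf_pfams = set(), set()
        if category == "ortholog":
            shared = (f"MOG{i:05d}", 33208, "Metazoa")
            root = (f"ROG{i:05d}", 1, "root")
            seq_ogs |= {shared, root}
            morf_ogs |= {shared, root}
            seq_pfams |= {f"PF{i:05d}a"}
            morf_pfams |= {f"PF{i:05d}a"}
        elif category == "protein_family":
            shared = (f"KOG{i:05d}", 2759, "Eukaryota")
            seq_ogs |= {shared, (f"MA{i:05d}", 33208, "Metazoa")}
            morf_ogs |= {shared, (f"MB{i:05d}", 33208, "Metazoa")}
            seq_pfams |= {f"PF{i:05d}a"}
            morf_pfams |= {f"PF{i:05d}a"}
        elif category == "pfam_majority":
            seq_ogs |= {(f"SA{i:05d}", 1, "root")}
            morf_ogs |= {(f"SB{i:05d}", 1, "root")}
            seq_pfams |= {f"PF{i:05d}a", f"PF{i:05d}b"}
            morf_pfams |= {f"PF{i:05d}b", f"PF{i:05d}x"}
        else:  # no_agreement
            seq_ogs |= {(f"NA{i:05d}", 1, "root")}
            morf_ogs |= {(f"NB{i:05d}", 1, "root")}
            seq_pfams |= {f"PF{i:05d}a", f"PF{i:05d}b", f"PF{i:05d}c"}
            morf_pfams |= {f"PF{i:05d}c"}  # 1/3 < half
        seq_profiles.append(
            OrthologyProfile(
                protein_id=protein,
                og_memberships=frozenset(seq_ogs),
                pfam_domains=frozenset(seq_pfams),
                preferred_name=seq_name,
            )
        )
        morf_profiles.append(
            OrthologyProfile(
                protein_id=protein,
                og_memberships=frozenset(morf_ogs),
                pfam_domains=frozenset(morf_pfams),
                preferred_name=morf_name,
            )
        )
        truth_rows.append([protein, category, "true" if same else "false"])

    seq_path = out / "seq.annotations.tsv"
    morf_path = out / "morf.annotations.tsv"
    truth_path = out / "truth_categories.tsv"
    write_emapper_table(seq_profiles, seq_path)
    write_emapper_table(morf_profiles, morf_path)
    _write_tsv(truth_path, ["protein", "category", "same_name"], truth_rows)
    return {"seq": seq_path, "morf": morf_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# CDS cohort


def _codon_weights(target_gc: float, rscu_bias: float, rng_sign: int) -> np.ndarray:
    """Codon sampling weights hitting an expected per-base GC target.

    Weights are exp(beta * GC(codon)); beta is solved so the expected GC
    fraction equals ``target_gc``.  ``rscu_bias`` adds an extra within-
    family preference (alternating sign over each family's codons) that
    shifts RSCU without moving GC much.
    """
    codons = np.array(_ALL_SENSE_CODONS)
    gc_counts = np.array([c.count("G") + c.count("C") for c in codons], float)
    pref = np.zeros(len(codons))
    if rscu_bias:
        index = {c: k for k, c in enumerate(codons)}
        for family in SYNONYMOUS_FAMILIES.values():
            for j, c in enumerate(family):
                pref[index[c]] = rscu_bias * (1 if (j + rng_sign) % 2 else -1)

    def expected_gc(beta: float) -> float:
        w = np.exp(beta * gc_counts + pref)
        p = w / w.sum()
        return float((p * gc_counts).sum() / 3.0)

    lo, hi = -30.0, 30.0
    if not expected_gc(lo) < target_gc < expected_gc(hi):
        raise ValueError(f"infeasible GC target {target_gc}")
    beta = brentq(lambda b: expected_gc(b) - target_gc, lo, hi, xtol=1e-10)
    w = np.exp(beta * gc_counts + pref)
    return w / w.sum()


def make_cds_cohort(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """CDS FASTA with background genes plus planted foreign-composition genes.

    Background genes draw per-gene GC targets from
    ``Normal(gc_background, gc_sd)``; foreign genes from the same model
    shifted by ``gc_shift`` (and optionally RSCU-biased).  Also writes a
    candidate id list, per-species best-hit tables for the presence
    matrix, and a truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not 0.05 < spec.gc_background < 0.95:
        raise ValueError(f"infeasible background GC {spec.gc_background}")
    if not 0.05 < spec.gc_background + spec.gc_shift < 0.95:
        raise ValueError(
            f"infeasible foreign GC {spec.gc_background + spec.gc_shift}"
        )
    rng = _rng(spec, 3)
    n_total = spec.n_genes + spec.n_foreign
    foreign = set(range(spec.n_genes, n_total))
    fasta_path = out / "cds.fasta"
    truth_rows = []
    codon_array = np.array(_ALL_SENSE_CODONS)
    with open(fasta_path, "wt", encoding="utf-8") as fh:
        for i in range(n_total):
            gene = f"cds{i:05d}"
            is_foreign = i in foreign
            base = spec.gc_background + (spec.gc_shift if is_foreign else 0.0)
            target_gc = float(
                np.clip(rng.normal(base, spec.gc_sd), 0.10, 0.90)
            )
            bias = spec.rscu_shift if is_foreign else 0.0
            weights = _codon_weights(target_gc, bias, rng_sign=i % 2)
            n_codons = int(rng.integers(spec.min_codons, spec.max_codons + 1))
            body = "".join(rng.choice(codon_array, size=n_codons, p=weights))
            seq = "ATG" + body + "TAA"
            fh.write(f">{gene}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
            truth_rows.append(
                [gene, f"{target_gc:.4f}", "true" if is_foreign else "false"]
            )

    candidates_path = out / "candidates.txt"
    with open(candidates_path, "wt", encoding="utf-8") as fh:
        for i in sorted(foreign):
            fh.write(f"cds{i:05d}\n")

    # per-species best-hit tables over the candidate genes
    species_paths = {}
    for s in range(spec.n_species):
        species = f"sponge_sp{s:02d}"
        path = out / f"hits_{species}.tsv"
        with open(path, "wt", encoding="utf-8") as fh:
            for i in sorted(foreign):
                if rng.random() >= spec.species_presence:
                    continue
                for _rep in range(int(rng.integers(1, 3))):
                    bits = round(float(rng.uniform(90, 420)), 1)
                    aln = int(rng.integers(100, 500))
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in [
                                f"cds{i:05d}", f"{species}_t{i:05d}",
                                f"{rng.uniform(0.3, 0.8):.3f}", aln,
                                int(rng.integers(0, aln)), int(rng.integers(0, 8)),
                                1, aln, 1, aln,
                                f"{10 ** (-bits / 10):.3e}", f"{bits:.1f}",
                            ]
                        )
                        + "\n"
                    )
        species_paths[species] = path

    truth_path = out / "truth_cds.tsv"
    _write_tsv(truth_path, ["gene", "target_gc", "foreign"], truth_rows)
    return {
        "fasta": fasta_path,
        "candidates": candidates_path,
        "species_tables": species_paths,
        "truth": truth_path,
    }


# ---------------------------------------------------------------------------
# structure models


def helix_coords(n_residues: int, rise: float = 1.5, radius: float = 2.3,
                 twist_deg: float = 100.0) -> np.ndarray:
    """Ideal alpha-helix C-alpha trace."""
    i = np.arange(n_residues)
    angle = np.deg2rad(twist_deg) * i
    return np.column_stack(
        [radius * np.cos(angle), radius * np.sin(angle), rise * i]
    )


def make_models(
    spec: FixtureSpec, out_dir: str | Path, ids: Optional[Sequence[str]] = None
) -> dict:
    """PDB model files with planted mean pLDDT and helix/globule labels.

    Every residue of a model carries the same pLDDT value (already at
    B-factor precision), so the planted mean is recovered exactly on
    re-parse; coordinates are pre-rounded to the PDB's 3 decimals so the
    files round-trip losslessly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 4)
    if ids is None:
        ids = [f"m{i:04d}" for i in range(spec.n_models)]
    n = len(ids)
    n_helix = round(spec.helix_fraction * n)
    labels = np.array(["helix"] * n_helix + ["globule"] * (n - n_helix))
    labels = labels[rng.permutation(n)]
    n_folded = round(spec.folded_fraction * n)
    folded = np.zeros(n, dtype=bool)
    folded[rng.permutation(n)[:n_folded]] = True

    truth_rows = []
    paths = {}
    for k, model_id in enumerate(ids):
        n_res = int(rng.integers(spec.min_residues, spec.max_residues + 1))
        if labels[k] == "helix":
            coords = helix_coords(n_res)
        else:
            coords = rng.normal(0.0, 6.0, size=(n_res, 3))
        coords = np.round(coords, 3)
        plddt = round(
            float(rng.uniform(70.5, 95.0) if folded[k] else rng.uniform(40.0, 65.0)),
            2,
        )
        path = out / f"{model_id}.pdb"
        with open(path, "wt", encoding="utf-8") as fh:
            for r in range(n_res):
                resname = _AA3[int(rng.integers(len(_AA3)))]
                x, y, z = coords[r]
                fh.write(
                    f"ATOM  {r + 1:5d}  CA  {resname} A{r + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{plddt:6.2f}"
                    f"           C\n"
                )
            fh.write("TER\nEND\n")
        paths[model_id] = path
        truth_rows.append([model_id, f"{plddt:.2f}", labels[k], n_res])

    truth_path = out / "truth_models.tsv"
    _write_tsv(
        truth_path, ["model_id", "mean_plddt", "label", "n_residues"], truth_rows
    )
    return {"models": paths, "truth": truth_path, "dir": out}


# ---------------------------------------------------------------------------
# GO fixture (ontology + annotation tables)

_FIXTURE_OBO_TERMS = {
    # molecular_function toy DAG: root; two branches; a diamond at depth 2/3
    "GO:0000001": ("root activity", []),
    "GO:0000002": ("branch X", [("GO:0000001", "is_a")]),
    "GO:0000003": ("branch Y", [("GO:0000001", "is_a")]),
    "GO:0000004": ("leaf Z", [("GO:0000002", "is_a")]),
    "GO:0000005": ("leaf W", [("GO:0000002", "is_a"), ("GO:0000003", "is_a")]),
    "GO:0000006": ("part P", [("GO:0000003", "part_of"), ("GO:0000002", "is_a")]),
    "GO:0000007": ("deep D", [("GO:0000004", "is_a")]),
    "GO:0000008": ("deep E", [("GO:0000005", "is_a")]),
}


def write_fixture_obo(path: str | Path) -> None:
    """Write the small deterministic molecular-function ontology."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        for term_id, (name, parents) in _FIXTURE_OBO_TERMS.items():
            fh.write("[Term]\n")
            fh.write(f"id: {term_id}\nname: {name}\n")
            fh.write("namespace: molecular_function\n")
            for pid, rel in parents:
                if rel == "is_a":
                    fh.write(f"is_a: {pid} ! parent\n")
                else:
                    fh.write(f"relationship: part_of {pid} ! parent\n")
            fh.write("\n")


def make_go_tables(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Synthetic ontology plus paired GO annotation tables.

    Plants per-protein overlap classes (identical / partial / disjoint)
    in equal thirds over ``n_proteins`` (capped at 60 for this fixture).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 5)
    obo_path = out / "synthetic.obo"
    write_fixture_obo(obo_path)
    terms = [t for t in _FIXTURE_OBO_TERMS if t != "GO:0000001"]
    n = min(spec.n_proteins, 60)
    counts = _exact_counts(
        n, {"identical": 1 / 3, "partial": 1 / 3, "disjoint": 1 / 3}
    )
    classes = [c for c in counts for _ in range(counts[c])]
    classes = [classes[i] for i in rng.permutation(n)]
    seq_rows, morf_rows, truth_rows = [], [], []
    for i in range(n):
        protein = f"p{i:05d}"
        cls = classes[i]
        pool = list(rng.permutation(terms))
        if cls == "identical":
            a = set(pool[:2])
            b = set(a)
        elif cls == "partial":
            a = {pool[0], pool[1]}
            b = {pool[1], pool[2]}
        else:
            a = {pool[0]}
            b = {pool[1]}
        seq_rows.append([protein, ",".join(sorted(a))])
        morf_rows.append([protein, ",".join(sorted(b))])
        truth_rows.append([protein, cls])
    seq_path = out / "seq_go.tsv"
    morf_path = out / "morf_go.tsv"
    truth_path = out / "truth_go.tsv"
    with open(seq_path, "wt", encoding="utf-8") as fh:
        fh.writelines("\t".join(r) + "\n" for r in seq_rows)
    with open(morf_path, "wt", encoding="utf-8") as fh:
        fh.writelines("\t".join(r) + "\n" for r in morf_rows)
    _write_tsv(truth_path, ["protein", "overlap"], truth_rows)
    return {"obo": obo_path, "seq": seq_path, "morf": morf_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# EC consistency fixture


def make_ec_tables(spec: FixtureSpec, out_dir: str | Path, n_queries: int = 50) -> dict:
    """Hit tables with EC annotations planting perfect top-range consistency.

    Every query's near-top hits (within the upper 10% of its score range)
    carry the best hit's exact EC number, so the planted per-query mean
    agreement depth is 4.0; low-score hits carry unrelated ECs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 6)
    path = out / "hits_ec.tsv"
    truth_rows = []
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("query_id\tbit_score\tec_numbers\n")
        for i in range(n_queries):
            query = f"e{i:04d}"
            best = float(rng.uniform(300, 500))
            low = float(rng.uniform(60, 150))
            ec = (
                f"{rng.integers(1, 7)}.{rng.integers(1, 9)}."
                f"{rng.integers(1, 9)}.{rng.integers(1, 99)}"
            )
            fh.write(f"{query}\t{best:.1f}\t{ec}\n")
            for _k in range(int(rng.integers(1, 3))):
                near = best - float(rng.uniform(0.1, 0.08 * (best - low)))
                fh.write(f"{query}\t{near:.1f}\t{ec}\n")
            for _k in range(int(rng.integers(1, 4))):
                other = (
                    f"{rng.integers(1, 7)}.{rng.integers(1, 9)}."
                    f"{rng.integers(1, 9)}.{rng.integers(1, 99)}"
                )
                fh.write(f"{query}\t{low - rng.uniform(0, 30):.1f}\t{other}\n")
            truth_rows.append([query, "4.0"])
    truth_path = out / "truth_ec.tsv"
    _write_tsv(truth_path, ["query", "mean_depth"], truth_rows)
    return {"hits_ec": path, "truth": truth_path}


def simulate_all(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Run every generator into subdirectories of ``out_dir``."""
    out = Path(out_dir)
    result = {
        "hits": make_hit_tables(spec, out / "hits"),
        "annotations": make_annotation_tables(spec, out / "annotations"),
        "cds": make_cds_cohort(spec, out / "cds"),
        "go": make_go_tables(spec, out / "go"),
        "ec": make_ec_tables(spec, out / "ec"),
    }
    # models named after the hit-table queries so triage can join them
    queries = [f"q{i:05d}" for i in range(min(spec.n_queries, spec.n_models))]
    result["models"] = make_models(spec, out / "models", ids=queries)
    manifest = {
        kind: {
            k: str(Path(v).relative_to(out))
            for k, v in paths.items()
            if not isinstance(v, dict)
        }
        for kind, paths in result.items()
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return result
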