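# morfkit

Structure-similarity protein annotation transfer — and the evaluation
machinery around it — for sparsely annotated proteomes.

Sequence-based orthology inference loses power at long evolutionary
distances: many proteins of early-branching animals (sponges, in the
motivating use case) share only 10–20% sequence identity with anything
characterized. Predicted structures change that. Searching a proteome's
predicted models against structure databases yields, for each query, a
best structural match — a **morpholog** — whose functional annotation
can be transferred to the query even when sequence similarity is
undetectable.

`morfkit` implements the computational core of that workflow and its
quality controls:

- **Hit-table post-processing** (`morfkit.hits`): parse 12-column
  tabular structure-search output, keep the hit with the highest
  corrected bit score per database, aggregate databases, impose a bit
  score cutoff (default e⁵ ≈ 148.41, strict `>`), transfer the best
  target's annotation to the query, collapse isoforms to genes, and
  compose display names with sequence-derived annotation taking
  priority over structure-derived.
- **Homology agreement** (`morfkit.agreement`): classify each protein's
  sequence-vs-structure annotation pair as *ortholog* (shared
  orthologous group at a narrow clade, default Metazoa), *protein
  family* (shared group at Eukaryota/root), *≥50% shared PFAM domains*,
  or *no agreement*; plus the taxon-exclusion self-annotation benchmark.
- **EC agreement** (`morfkit.ec`): four-field EC codes, common-prefix
  agreement depth (0–4), and top-score-range consistency — the mean
  agreement depth between the best hit and all hits in the upper
  q-fraction of the bit-score range (default q = 0.9).
- **GO semantics** (`morfkit.go`): OBO parsing, raw-set overlap classes,
  Wang topological similarity (S-values as max edge-weight path
  products, weights is_a = 0.8 / part_of = 0.6), Average-Best-Match
  gene similarity, and term depth (longest is_a path from the root).
- **Compositional HGT screening** (`morfkit.composition`): GC content,
  RSCU, Wright's effective number of codons, a z-score screen of
  candidate genes against the transcriptome background, and
  cross-species best-hit presence matrices.
- **Structure metrics** (`morfkit.structure`): Cα/pLDDT model parsing
  (pLDDT from the B-factor column), confidence bands, Kabsch
  superposition RMSD on explicit atom pairings, a gyration-tensor
  elongation score for long-helix detection, GRAVY / isoelectric point /
  instability index, and novel-fold triage (unannotated + mean pLDDT
  > 70, partitioned by hit status and shape).
- **Synthetic fixtures** (`morfkit.fixtures`): seeded generators for
  every input format with planted ground truth, so the whole pipeline
  is testable offline.

## Worked example

Generate a synthetic study and run the annotation step:

```sh
morfkit simulate --preset all --seed 7 --out demo
morfkit annotate \
    --hits afdb=demo/hits/hits_afdb.tsv \
    --hits pdb=demo/hits/hits_pdb.tsv \
    --hits swissprot=demo/hits/hits_swissprot.tsv \
    --annotations demo/hits/morpholog_annotations.tsv \
    --isoform-map demo/hits/isoform_map.tsv \
    --out demo/assignments.tsv
morfkit agree \
    --seq demo/annotations/seq.annotations.tsv \
    --morf demo/annotations/morf.annotations.tsv \
    --out demo/agree.tsv
```

The annotate step prints

```
wrote 99 assignments to demo/assignments.tsv
```

one row per gene: the 200 isoform-level queries collapse two-to-one
into 100 genes, one of which (at this seed) has no structure-search hit
on either isoform and so never enters the hit tables. Each row carries
the gene's best database, best target, bit score, whether it cleared
the e⁵ cutoff, and the transferred name. The agreement step prints the
category composition of the planted cohort:

```
ortholog	0.5670
protein_family	0.3390
pfam_majority	0.0470
no_agreement	0.0470
```

i.e. 56.7% of proteins got the *same orthologous group* from both
annotation routes, a further 33.9% landed in the same gene family —
90.6% homologous in total — and the screen recovers exactly the
fractions the generator planted.

The other stages follow the same pattern (`morfkit ec-consistency`,
`morfkit go-compare`, `morfkit hgt-screen`, `morfkit struct-stats`,
`morfkit superpose`, `morfkit triage`); every command supports
`--log-level` and a plain-text `key=value` `--config` file.

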