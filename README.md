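# salmonigh

Nomenclature, classification and repertoire-annotation tooling for the
duplicated immunoglobulin heavy-chain (IGH) loci of salmonid fish
(Atlantic salmon *Salmo salar*, rainbow trout *Oncorhynchus mykiss*).

Salmonids carry **two large duplicated IGH loci** per haplotype (locus A and
locus B, a legacy of the salmonid whole-genome tetraploidization), each with
dozens to hundreds of variable (V) genes, many of them pseudogenes, plus
diversity (D), joining (J) and constant (C) genes organised into D-J-C
clusters (one per constant-gene isotype: mu/IgM, delta/IgD and the
fish-specific tau/IgT series). Annotating expressed antibody repertoires
(AIRRseq) against such loci requires a strict, consistent gene nomenclature
and curated germline reference directories. `salmonigh` implements that
machinery as a reusable library + CLI:

- **Gene-name grammar** (`igmodel`) — a bidirectional parser/renderer for
  symbols such as `IGHV6D-76` (V subgroup 6, locus B, position 76),
  `IGHD1T2D` (first diversity gene of the tau-2 cluster, locus B), `IGHDD`
  (the locus-B delta constant gene), `IGHD-5` (a dispersed diversity gene)
  and provisional `S` names; `format(parse(s)) == s` on every valid symbol.
- **Subgroup classification** (`subgroup_classifier`) — pairwise V-REGION
  nucleotide identity from global alignment; V subgroups as single-linkage
  clusters at the IMGT 75 % identity threshold; functionality calling
  (F / ORF / P with defect codes); recombination-signal (heptamer / 12-23
  spacer / nonamer) detection; IMGT unique-numbering gapping of V regions
  (anchors 23-C, 41-W, 89-hydrophobic, 104-C; CDR1 27–38, CDR2 56–65).
- **Positional nomenclature** (`locus_annotator`) — 5'→3' locus ordering,
  D/J-to-C cluster association (tau tags, dispersed-D detection), V-gene
  numbering by distance from the IGHM cluster, GFF3 and text locus maps.
- **Reference directories** (`refdir`) — "F+ORF" and "F+ORF+in-frame P"
  allele sets, FASTA serialization, census summaries, allele registration
  with provisional naming.
- **Repertoire annotation** (`repertoire`) — V/D/J assignment with explicit
  duplicate-gene ambiguity (co-optimal hits are reported as ties, never
  broken), junction/CDR3-IMGT extraction (positions 104–118 / 105–117),
  productivity calling, UMI consensus deduplication, usage and clonotype
  tables, AIRR rearrangement TSV output.
- **Synthetic data** (`simdata`) — germline loci with controlled subgroup
  structure, planted functionality defects and duplicated-locus copies;
  V-D-J rearranged reads with trimming, N additions, point mutations and
  full ground truth.
- **Variation & phylogeny** (`varcomp`) — SNP/indel tallies with silent vs
  non-silent classification, Fisher/chi-square proportion comparison, UPGMA
  trees with bootstrap supports and Newick output.

Packaged fixtures transcribe the published census tables for both species
(gene counts per subgroup/locus/functionality, reference-directory allele
counts, D-J-C cluster tables, per-gene variant counts across 19 isogenic
trout lines, V-gene placements), so the headline numbers are reproducible
at desk scale without downloads.

## Worked example

```python
from salmonigh import datasets
from salmonigh.refdir import DirectorySetSpec, build_directory, summarize_gene_table

salmon = datasets.salmon_v_gene_table()          # 303 genes, 320 allele rows
print(summarize_gene_table(salmon, "locus"))
#  functionality   F  ORF    P  Total
#  locus_id
#  A              30    7  108    145
#  B              39    5  114    158
#  Total          69   12  222    303

directory = build_directory(salmon, DirectorySetSpec("F_ORF_INFRAME_P"))
print(len(directory))                            # 150  (76 F + 15 ORF + 59 in-frame P)
```

The census summary counts each of the 303 salmon V genes once under its best
allele functionality (the two genes carrying both an F and a P allele,
IGHV8-58 and IGHV2D-12, count as functional); the directory filter instead
works per allele, keeping every F and ORF allele plus pseudogene alleles
whose reading frame is open — 150 alleles for salmon, 77 for trout.

Annotating simulated reads end to end:

```python
from salmonigh.simdata import SimConfig, simulate_germline_locus, \
    directory_from_loci, simulate_repertoire
from salmonigh.repertoire import annotate_repertoire

cfg = SimConfig(seed=7, n_reads=200)
loci, table, truth = simulate_germline_locus(cfg)
dirs = {g: directory_from_loci(loci, group=g) for g in ("V", "D", "J")}
reads, read_truth = simulate_repertoire(dirs, cfg)
records, summary = annotate_repertoire([(r[0], r[1]) for r in reads], dirs)
print(summary)   # {'assigned': 200, 'ambiguous': 0, 'unassigned': 0, 'incomplete': 0, 'failed': 0}
```

With no mutations every V and J call matches the generator's truth table;
reads drawn from identical duplicated gene pairs come back as exact two-gene
ties.

A CLI mirrors the library: `igh classify`, `igh build-refdir`,
`igh annotate`, `igh simulate`, `igh tally-variants`, `igh tree`.

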