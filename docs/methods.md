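# Methods

This note documents the models, conventions and numerical choices behind
`salmonigh`, in the order a user meets them.

## The gene-name grammar

Salmonid IGH gene symbols encode locus duplication, cluster membership and
position in a compact string. The grammar implemented in `igmodel`:

| form | meaning |
|---|---|
| `IGHV<s>[D]-<p>` | V gene, subgroup *s*, position *p*; `D` marks locus B |
| `IGHV<s>[D]S<k>` | provisional (not yet localized) V gene |
| `IGHD<k>[T<m>][D]` | diversity gene, index *k* within its D-J-C cluster; `T<m>` tags a tau cluster, no tag means the mu/delta cluster |
| `IGHD-<p>[D]` | dispersed diversity gene (located among the V genes) |
| `IGHJ<k>[T<m>][D]` | joining gene (always cluster-associated) |
| `IGHM[D]`, `IGHD[D]`, `IGHT<n>[D]` | constant genes (mu, delta, tau series) |

The one ambiguity, `IGHD`, resolves by the presence of digits: bare `IGHD`
(or `IGHDD`) is the delta constant gene; a digit or hyphen makes it a
diversity gene. Allele references append `*NN` (zero-padded). Parsing and
rendering are exact inverses; a property test exercises 10,000 random valid
names. Printed-table typos in the source material are normalized at fixture
load through an explicit map (`IGHJIT4→IGHJ1T4`, `IGHJIT5→IGHJ1T5`,
`IGHJID→IGHJ1D`, `IGHV12D56/57→IGHV12D-56/-57`, a stray `IGH ` token), never
silently.

For provisional names the `S` index is stored in the `position` field with a
`provisional` flag; this keeps the invariant that V genes always carry a
position while leaving cluster indices untouched.

## Pairwise identity and the 75 % subgroup rule

V subgroups are defined by V-REGION nucleotide identity at the 75 %
threshold. The source material does not specify the alignment underlying
"percentage of identity", so the package fixes one and makes it
configurable: **global alignment, match +1 / mismatch 0, affine gaps
(open −4, extend −1), free terminal gaps**, with identity = identical
columns / aligned columns after stripping terminal-gap columns. This follows
common germline-gene practice (ungapped-equivalent scoring with mild indel
tolerance). Identity is symmetric and invariant under joint
reverse-complement; mutating exactly *k* of *n* positions yields identity
(n−k)/n.

Clustering is **single linkage**: subgroups are connected components of the
graph with an edge wherever identity ≥ threshold. Transitivity at the
boundary is therefore resolved permissively (a chain A–B–C at 0.8/0.8/0.7 is
one subgroup), which matches the notion that a subgroup is a set of genes
each similar to *some* member. De-novo labels are consecutive integers in
ascending order of each component's lexicographically smallest member —
deterministic but arbitrary; mapping onto the historical subgroup numbers
1–16 is done only by `assign_to_reference_subgroups` against a labeled
directory (ties broken toward the lower subgroup number, logged).

## Functionality calling

`classify_functionality` applies the standard three-way scheme:

- **P (pseudogene)** — reading-frame defects: in-frame stop codon
  (`STOP_CODON`), length not a codon multiple (`FRAMESHIFT`), missing
  leader initiation codon (`NO_INIT`), or V-REGION shorter than a floor
  (`TRUNCATED`, default 270 nt). `in_frame` is True iff no frameshift.
- **ORF** — open frame but defective flanking elements or anchors:
  no detectable recombination signal in the stored 3' flank
  (`RSS_DEFECT`), a curated splice-defect flag (`SPLICE_DEFECT` — this
  cannot be derived from a bare V-REGION, so it is honored from input, not
  predicted), or a non-canonical residue at IMGT anchor position 23, 41, 89
  or 104 (`CONSERVED_AA_CHANGE`; the check is limited to these four
  anchors).
- **F** — otherwise.

An RS defect on an otherwise-open frame is classed ORF (the standard
scientific-chart reading); `strict_flank_mode=True` switches to the
alternative reading that groups leader/RS defects with in-frame pseudogenes.

RSS detection scans for the heptamer consensus `CACAGTG` with the first
three bases required exact, then the nonamer `ACAAAAACC` at the expected
spacer (23 nt for V, 12 for D, ±1 nt), keeping the lowest-total-mismatch hit
with at most 2 mismatches per element.

## IMGT gapping

`gap_v_region` lays a translated V-REGION onto unique-numbering positions
1–104: FR1 = positions 1–26 (1st-CYS at 23), CDR1 in window 27–38 (≤12 aa),
FR2 = 39–55 (conserved TRP at 41), CDR2 in 56–65 (≤10 aa), FR3 = 66–104
(hydrophobic 89, 2nd-CYS 104 as the final residue). Both CYS anchors are
mandatory (error otherwise); the TRP is located by scanning the positions
compatible with a CDR1 of 0–12 aa, falling back to length arithmetic when
absent. CDR gaps fill from the loop top: the first ⌈len/2⌉ residues sit at
the window start, the rest at the end. Sequences between 82 and 104 aa are
representable; FR-internal indels are out of scope.

## Positional nomenclature

The numbering origin is **position 1 = the V gene closest to the IGHM D-J-C
cluster**, increasing 3'→5', one series per locus shared across subgroups —
inferred from the printed coordinate/name correspondence (the gene adjacent
to the cluster is `-1`, the most distal carries the largest number; V genes
between two clusters take the smallest positions). Dispersed D genes are
hyphen-numbered in the same direction. Cluster D and J genes are indexed
1..k in 5'→3' order within their cluster and carry the cluster's tau tag;
tau constant genes are numbered 1..n in 5'→3' order. Locus-B genes always
render with the `D` marker. Cluster membership is decided purely by gene
interleaving (the nearest downstream C gene with no intervening V gene —
no distance cutoff), with a per-fixture override for printed layouts where
a D set sits downstream of its tau gene; a D gene with intervening V genes
is DISPERSED, a J gene in that position is an error.

Re-numbering the 129 located trout V genes from their printed coordinates
reproduces every printed position on both chromosomes, after excluding the
two printed-position duplicates carried in the fixture with a
`position_anomaly` flag (both chr13 `IGHV1-39`/`IGHV13-39` print position
39; both chr12 `IGHV2D-11`/`IGHV5D-11` print position 11 — 49 and 80 genes
over 48 and 79 printed positions respectively). A reversed printed
coordinate pair encodes opposite polarity and is normalized to (min, max).

## Reference directories and census bookkeeping

Two set types: `F_ORF` and `F_ORF_INFRAME_P` (adds pseudogene alleles with
an open frame; out-of-frame P alleles are never included). Functionality is
honored **per allele**, so a gene with both an F and a P allele contributes
its F allele regardless of the sibling. Gene-level summaries count each gene
once under its best functionality (F > ORF > P); a census-style dual-count
presentation (`(+n)` in both classes) is available separately, matching the
printed tables. With `one_allele_per_gene`, each gene contributes its
lowest-numbered allele among those with the gene's best admitted
functionality. Allele numbers are assigned in registration order and never
reused. Directory FASTA headers use a 5-field pipe-delimited dialect
(allele | species | functionality | locus | region label) — the fields
consumed downstream.

The packaged salmon gene table is expanded deterministically from two
verbatim census transcriptions (gene counts per subgroup × locus ×
functionality; directory gene/allele counts). The expansion fixes the mixed
F/P genes as `*01 P (out of frame) + *02 F` and distributes the handful of
extra `*02`/`*03` alleles so that every printed total reproduces: 303 genes
(145 + 158, 16 subgroups), 150 directory alleles (76 F + 15 ORF + 59
in-frame P), 81 F+ORF genes, and 77/55 for trout (136 tree tips combined).
Gene placements in the expansion are synthetic (the censuses print no
coordinates) but respect the numbering rule.

## Repertoire annotation

Reads are assigned a V by semi-global alignment (edlib, edit distance) of
every directory V allele against both read strands; all co-optimal hits are
returned — **ties between near-identical duplicated genes are reported,
never silently broken**. Reads whose best identity falls below a floor
(default 0.60) are flagged unassigned. The junction runs from the V-REGION
2nd-CYS codon (position 104, mapped through the alignment) to the J-REGION
[W/F]-G-x-G codon (position 118, located by translating the J germline);
CDR3-IMGT is the interior (105–117). D is the longest exact substring match
(forward strand, ≥5 nt by default) between the junction interior and any
D-REGION, omitted when no qualifying match exists; length ties break to the
lexicographically smallest allele. Productivity requires an in-frame
(length ≡ 0 mod 3), stop-free junction. Usage tables count only productive
records, a k-way tie contributing 1/k to each tied gene (the declared
convention; first-gene counting is the documented alternative); clonotypes
key on (V gene, J gene, CDR3 nucleotide sequence). UMI groups collapse by
per-column majority vote on same-length members, longest member otherwise.

Because the 2nd-CYS codon anchors the junction, V-end trimming beyond 3 nt
destroys the anchor and part of a short retained D core can be absorbed into
the anchor codon slot; the round-trip tests therefore score D recovery over
reads whose planted D is *identifiable in principle* — V trim ≤ 3 and the
retained core the strict longest match in the true junction interior,
computed from the generator's truth alone. V and J recovery is checked on
every read.

## The simulator

`simulate_germline_locus` draws subgroup ancestor V-REGIONs on the exact
IMGT architecture above (anchors planted, tryptophan excluded outside its
anchor so motif search is unambiguous), rejection-samples ancestors until
all pairwise identities sit at or below the between-subgroup ceiling
(default 0.65), then derives each member by exactly
⌈(1 − within-target)/2 × L⌉ substitutions at non-anchor, non-stop-creating
positions (default within-target 0.85 → pairwise member identity ≈ 0.85,
always above the 0.75 threshold; the ceiling/threshold/target ordering is
enforced). Defects are planted per configured fractions: pseudogenes get an
in-frame stop or a single-base deletion (50/50), ORFs a heptamer seed
mutation (`CACAGTG→CTCAGTG`) in the 3' flank. D-J-C clusters are laid out
as one tau cluster plus the mu/delta cluster; an optional locus-B copy
diverges each V gene by a per-gene divergence (default 0.02; 0 yields
identical twins for ambiguity testing) and renders all names with the `D`
marker. Everything is deterministic under the config seed.

`simulate_repertoire` samples V/D/J alleles (configurable V weights), trims
uniformly (V 3' 0–5 nt, both D ends 0–6 nt, J 5' 0–5 nt), inserts N
additions of geometric-mean length 3 on each side of D (unbiased over
ACGT, no P-nucleotides), applies uniform per-base substitutions at the
configured rate (a deliberate simplification — no somatic-hypermutation
hotspots), and optionally attaches UMIs with a duplication factor. Every
read carries a truth row including trims, insertion strings and mutated
positions.

What the simulator does **not** emulate: sequencing error profiles,
hotspot-biased hypermutation, gene conversion, inverted D usage, allelic
variation within a locus, or the chromosomal-scale coordinate structure of
real assemblies. Tests passing on simulated data therefore demonstrate the
correctness of the algorithms under the stated generative model, not
performance on real AIRRseq runs; the repertoire percentages observed in
real datasets depend on those datasets and are not reproduced here.

## Variation tallies and phylogeny

SNP effects are computed by codon substitution in the gene's reading frame
(silent iff the amino acid is unchanged); pseudogene variants without a
defined frame count toward SNP totals but not non-silent totals. Class
totals (functional vs pseudogene × chromosome) are sums over member genes
by construction. The silent/non-silent proportion comparison reports
Fisher's exact two-sided p-value (primary; the source states only "not
significantly different" without naming a test) plus the continuity-
corrected chi-square, with a significance flag at α = 0.05 that downstream
logic never hard-codes.

UPGMA is implemented in-package (average linkage; node height = half the
merged-pair average distance, hence ultrametric output) with a declared
deterministic tie-break: equal minimal distances resolve toward the pair
whose smallest member labels sort first. Distances for sequence trees are
1 − pairwise identity. Bootstrap resamples alignment columns with
replacement (requires equal-length sequences), rebuilds trees on normalized
Hamming distances, and reports clade support as a percentage over
replicates, deterministic under the seed. Tests cross-check topologies and
heights against an exhaustive average-linkage oracle (n ≤ 6) and against
dendropy's UPGMA on random matrices.

## Problem sizes and defaults

Desk-scale defaults keep the whole suite and the acceptance script in
seconds: 3 subgroups × 4 genes, 300-nt V regions, 4 + 2 D and 3 + 2 J
genes, 80–400 reads per experiment (200 mutation-free, 400 at the 2 %
mutation rate used for the ≥95 % gene-recovery bound, where multinomial
error at n = 400 is ~1 %), 200 random matrices for the clustering oracle,
10,000 names for the grammar round trip, 50-replicate bootstraps on 6
taxa in tests. Census-derived results use the full packaged fixtures
(303 + 129 genes, 150 + 77 directory alleles).

## Known limitations

- The identity definition (alignment parameters, ungapped vs gapped input)
  is a declared choice; published subgroup boundaries could differ under a
  different alignment model.
- IMGT gapping handles standard-architecture V regions only (no
  FR-internal indels, single CYS23/CYS104 placement).
- D assignment is exact-substring and forward-strand; heavily trimmed or
  mutated D segments, and inverted D usage, are not called.
- The printed-census expansion invents gene placements; only
  subgroup/locus/functionality/allele structure is authoritative there.
- `IGHMD` functionality is recorded as "unstated" (blank in the printed
  table); the printed trout locus-B constant-gene count differs between
  sections of the source (3 vs 5) and both numbers are kept with their
  provenance rather than reconciled.
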