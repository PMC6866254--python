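"""Germline variation tallies and comparative phylogenetics.

Tallies SNP/indel variants within IGHV genes across sequenced lines
(silent vs non-silent classified by codon substitution in the gene's
reading frame), compares non-silent proportions between regions (Fisher's
exact test plus chi-square with continuity correction), and builds UPGMA
trees (average linkage, ultrametric) with column-bootstrap support values
and Newick output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .igmodel import GeneName, GeneTable, format_gene_name, parse_gene_name

__all__ = [
    "VariantRecord",
    "VariantTally",
    "ProportionTestResult",
    "TreeNode",
    "tally_variants",
    "tally_from_counts",
    "compare_ns_proportions",
    "upgma_tree",
    "distance_matrix_from_identity",
    "to_newick",
]


@dataclass(frozen=True)
class VariantRecord:
    """One germline variant within a V-REGION (1-based position)."""

    gene: GeneName
    position: int
    ref: str
    alt: str
    kind: str = ""  # SNP | INDEL (derived when empty)
    effect: str = "NA"  # SILENT | NON_SILENT | NA

    def __post_init__(self) -> None:
        kind = self.kind or ("SNP" if len(self.ref) == len(self.alt) == 1 else "INDEL")
        object.__setattr__(self, "kind", kind)
        if kind == "SNP" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("SNP requires single-base ref and alt")
        if kind == "INDEL" and len(self.ref) == len(self.alt):
            raise ValueError("INDEL requires ref and alt of different lengths")


@dataclass
class VariantTally:
    """Per-gene and per-class SNP / non-silent / indel counts."""

    per_gene: pd.DataFrame
    per_class: pd.DataFrame  # index (class, chromosome), columns snp/ns/indel

    def class_total(self, cls: str, chromosome: str, column: str) -> int:
        return int(self.per_class.loc[(cls, chromosome), column])


def _snp_effect(seq: str, position: int, ref: str, alt: str, frame: int) -> str:
    """SILENT iff the codon substitution leaves the amino acid unchanged."""
    from Bio.Seq import Seq

    idx = position - 1
    if seq[idx].upper() != ref.upper():
        raise ValueError(f"reference base mismatch at position {position}")
    offset = idx - frame
    codon_start = frame + 3 * (offset // 3)
    codon = seq[codon_start : codon_start + 3]
    if len(codon) < 3:
        return "NA"
    mutated = list(codon)
    mutated[idx - codon_start] = alt
    before = str(Seq(codon).translate())
    after = str(Seq("".join(mutated)).translate())
    return "SILENT" if before == after else "NON_SILENT"


def tally_variants(
    variants: Sequence[VariantRecord],
    table: GeneTable,
    frames: Optional[Dict[str, int]] = None,
) -> VariantTally:
    """Aggregate variants per gene and per class (functional vs pseudogene).

    SNP effects are computed by codon substitution in the gene's reading
    frame (``frames`` maps gene symbol to frame offset, default 0); variants
    of genes with no defined frame (pseudogenes by default) get effect NA --
    counted in the SNP totals but excluded from the non-silent totals.
    Raises when a variant falls outside its gene's bounds or its gene is
    absent from the table.
    """
    frames = frames or {}
    df = table.df.drop_duplicates("name").set_index("name")
    rows = []
    for v in variants:
        name = format_gene_name(v.gene)
        if name not in df.index:
            raise KeyError(f"variant gene {name} not in gene table")
        g = df.loc[name]
        length = int(g["stop"]) - int(g["start"]) + 1
        if not (1 <= v.position <= length):
            raise ValueError(f"variant position {v.position} outside gene {name}")
        functionality = g["functionality"]
        cls = "functional" if functionality in ("F", "ORF") else "pseudogene"
        effect = v.effect
        if v.kind == "SNP" and effect == "NA":
            seq = g.get("sequence")
            frame = frames.get(name)
            if isinstance(seq, str) and seq and (frame is not None or cls == "functional"):
                effect = _snp_effect(seq, v.position, v.ref, v.alt, frame or 0)
        rows.append(
            {
                "name": name,
                "chromosome": g["chromosome"],
                "class": cls,
                "snp": int(v.kind == "SNP"),
                "ns": int(v.kind == "SNP" and effect == "NON_SILENT"),
                "indel": int(v.kind == "INDEL"),
            }
        )
    if rows:
        per_variant = pd.DataFrame(rows)
        per_gene = per_variant.groupby(["name", "chromosome", "class"], as_index=False).sum()
    else:
        per_gene = pd.DataFrame(columns=["name", "chromosome", "class", "snp", "ns", "indel"])
    per_class = (
        per_gene.groupby(["class", "chromosome"])[["snp", "ns", "indel"]].sum()
        if len(per_gene)
        else pd.DataFrame(columns=["snp", "ns", "indel"])
    )
    return VariantTally(per_gene=per_gene, per_class=per_class)


def tally_from_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Sum a per-gene variant-count table into per-class, per-chromosome
    totals (columns snp, ns, indel; NS of pseudogenes is NA and sums as 0)."""
    out = df.copy()
    out["ns"] = pd.to_numeric(out["ns"], errors="coerce").fillna(0).astype(int)
    totals = out.groupby(["chromosome", "class"])[["snp", "ns", "indel"]].sum()
    # conservation check: class totals must equal member sums by construction
    return totals


@dataclass
class ProportionTestResult:
    table: np.ndarray
    fisher_p: float
    chi2_statistic: float
    chi2_p: float
    significant: bool
    alpha: float = 0.05


def compare_ns_proportions(
    ns_a: int, silent_a: int, ns_b: int, silent_b: int, alpha: float = 0.05
) -> ProportionTestResult:
    """Compare non-silent vs silent SNP proportions between two regions.

    Builds the 2x2 table [[ns_a, silent_a], [ns_b, silent_b]] and reports
    Fisher's exact two-sided p-value (primary) and the continuity-corrected
    chi-square statistic (secondary).  The significance flag uses ``alpha``
    but is reported only, never acted on.
    """
    from scipy import stats

    table = np.array([[ns_a, silent_a], [ns_b, silent_b]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin in 2x2 table")
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=True)
    return ProportionTestResult(
        table=table,
        fisher_p=float(fisher_p),
        chi2_statistic=float(chi2),
        chi2_p=float(chi2_p),
        significant=bool(fisher_p < alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class TreeNode:
    """Node of an ultrametric (UPGMA) tree."""

    height: float = 0.0
    label: Optional[str] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None and self.left is None

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def clades(self) -> List[frozenset]:
        """Leaf sets of all internal nodes (excluding the trivial ones)."""
        out = []

        def rec(node: "TreeNode"):
            if node.is_leaf:
                return
            out.append(frozenset(node.leaves()))
            rec(node.left)
            rec(node.right)

        rec(self)
        return out


def _upgma(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Average-linkage agglomeration; ties broken toward the
    lexicographically smallest (sorted) label pair."""
    clusters: Dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in clusters}
    mins = {i: labels[i] for i in clusters}  # smallest member label per cluster
    d = {
        (i, j): float(dist[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        best_key = min(
            d,
            key=lambda k: (d[k], *sorted((mins[k[0]], mins[k[1]]))),
        )
        i, j = best_key
        h = d[best_key] / 2.0
        node = TreeNode(height=h, left=clusters[i], right=clusters[j])
        del d[best_key]
        new_d = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            new_d[k] = (dik * sizes[i] + djk * sizes[j]) / (sizes[i] + sizes[j])
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        mins[next_id] = min(mins.pop(i), mins.pop(j))
        del clusters[i], clusters[j]
        clusters[next_id] = node
        for k, val in new_d.items():
            d[(min(k, next_id), max(k, next_id))] = val
        next_id += 1
    return next(iter(clusters.values()))


def upgma_tree(
    dist: np.ndarray,
    labels: Sequence[str],
    bootstrap: Optional[Tuple[Dict[str, str], int, int]] = None,
) -> TreeNode:
    """UPGMA clustering of a symmetric non-negative distance matrix.

    Node height is half the merged-pair average distance, so root-to-leaf
    path lengths are all equal (ultrametric).  With
    ``bootstrap=(alignment, n_replicates, seed)`` -- ``alignment`` mapping
    label to an equal-length (gapped) sequence -- alignment columns are
    resampled with replacement, per-replicate trees rebuilt on normalized
    Hamming distances, and each internal node annotated with its clade
    support as a percentage over replicates.  Deterministic under the seed.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape must match labels")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if dist.min() < 0:
        raise ValueError("distances must be non-negative")
    tree = _upgma(dist, labels)
    if bootstrap is None:
        return tree
    alignment, n_rep, seed = bootstrap
    seqs = [alignment[lab] for lab in labels]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("bootstrap requires aligned sequences of equal length")
    arr = np.array([list(s) for s in seqs])
    L = arr.shape[1]
    # per-column pairwise mismatch indicators, for fast replicate distances
    mism = (arr[:, None, :] != arr[None, :, :]).astype(np.float32)
    rng = np.random.default_rng(seed)
    counts: Dict[frozenset, int] = {c: 0 for c in tree.clades()}
    for _ in range(n_rep):
        cols = rng.integers(0, L, size=L)
        rep_dist = mism[:, :, cols].mean(axis=2)
        np.fill_diagonal(rep_dist, 0.0)
        rep_tree = _upgma(rep_dist, labels)
        for clade in rep_tree.clades():
            if clade in counts:
                counts[clade] += 1

    def annotate(node: TreeNode):
        if node.is_leaf:
            return
        node.support = 100.0 * counts[frozenset(node.leaves())] / n_rep
        annotate(node.left)
        annotate(node.right)

    annotate(tree)
    return tree


def distance_matrix_from_identity(identity: np.ndarray) -> np.ndarray:
    """Distance = 1 - pairwise identity."""
    return 1.0 - np.asarray(identity, dtype=float)


def to_newick(node: TreeNode, parent_height: Optional[float] = None) -> str:
    """Render a tree as Newick; internal bootstrap supports become labels."""
    if node.is_leaf:
        bl = (parent_height - node.height) if parent_height is not None else 0.0
        return f"{node.label}:{bl:.6g}"
    inner = f"({to_newick(node.left, node.height)},{to_newick(node.right, node.height)})"
    label = f"{node.support:.0f}" if node.support is not None else ""
    if parent_height is None:
        return f"{inner}{label};"
    return f"{inner}{label}:{parent_height - node.height:.6g}"
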