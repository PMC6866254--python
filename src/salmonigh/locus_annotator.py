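"""Positional nomenclature for a located, subgroup-labeled IGH gene set.

Turns a :class:`~salmonigh.igmodel.LocusModel` into named genes following the
salmonid conventions: genes are ordered 5'->3' along the locus reading
direction (descending genomic coordinate on REV loci), each D and J gene is
associated with the nearest downstream constant gene (its D-J-C cluster,
tagged ``T<m>`` for tau clusters), D genes stranded among the V genes are
DISPERSED and hyphen-numbered, and V genes are numbered in a single
positional series per locus with position 1 closest to the IGHM D-J-C
cluster (increasing 3'->5').  Every gene on locus B carries the ``D``
(duplicated) marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import pandas as pd

from .igmodel import (
    GeneName,
    GeneTable,
    GermlineGene,
    LocusModel,
    format_gene_name,
)
from .subgroup_classifier import SubgroupAssignment

__all__ = [
    "LocusLayout",
    "ClusterAssociation",
    "DISPERSED",
    "order_genes",
    "associate_dj_to_c",
    "assign_positional_names",
    "write_gff3",
    "format_locus_map",
]

DISPERSED = "DISPERSED"


@dataclass
class LocusLayout:
    """Genes of one locus sorted in biological 5'->3' order."""

    locus: LocusModel
    order: List[GermlineGene]

    def index(self, gene: GermlineGene) -> int:
        return self.order.index(gene)


def order_genes(locus: LocusModel) -> LocusLayout:
    """Sort genes in biological 5'->3' order of the locus.

    Ascending genomic coordinate for FWD loci, descending for REV; stable
    tie-break by start coordinate then name.  Raises if a gene lies outside
    the locus span.
    """
    lo, hi = locus.span
    for g in locus.genes:
        if g.start < lo or g.stop > hi:
            raise ValueError(f"gene {format_gene_name(g.name)} outside locus span")
    rev = locus.orientation == "REV"
    ordered = sorted(
        locus.genes,
        key=lambda g: (-g.midpoint if rev else g.midpoint, g.start, format_gene_name(g.name)),
    )
    return LocusLayout(locus=locus, order=ordered)


@dataclass
class ClusterAssociation:
    """D/J gene -> constant-gene cluster mapping.

    ``assignments`` maps each D/J gene (by identity) to its associated C gene
    or to :data:`DISPERSED` (D genes stranded among the V genes only);
    ``members`` lists each cluster's D/J genes in 5'->3' order.
    """

    assignments: Dict[int, object] = field(default_factory=dict)  # id(gene) -> C gene | DISPERSED
    members: Dict[int, List[GermlineGene]] = field(default_factory=dict)  # id(C gene) -> genes
    _genes: Dict[int, GermlineGene] = field(default_factory=dict)

    def cluster_of(self, gene: GermlineGene):
        return self.assignments[id(gene)]


def associate_dj_to_c(
    layout: LocusLayout, overrides: Optional[Dict[str, str]] = None
) -> ClusterAssociation:
    """Associate each D and J gene with its D-J-C cluster.

    Each D/J gene maps to the nearest constant gene downstream of it (5'->3')
    provided no V gene lies between them; a D gene with an intervening V gene
    is DISPERSED; a J gene in that situation is an error.  The delta constant
    gene shares the IGHM cluster (it has no D-J set of its own), so genes
    whose nearest downstream C is the delta gene are attached to the mu
    cluster.  ``overrides`` maps a gene symbol to the symbol of the C gene it
    must be associated with (used for printed layouts where a D-J set sits
    downstream of its tau gene).
    """
    order = layout.order
    c_positions = [i for i, g in enumerate(order) if g.name.group == "C"]
    if not c_positions:
        raise ValueError("layout contains no constant gene")
    overrides = overrides or {}
    by_name = {format_gene_name(g.name): g for g in order}

    # the mu gene anchors the shared mu/delta cluster
    mu = next((order[i] for i in c_positions if order[i].name.isotype == "M"), None)

    assoc = ClusterAssociation()
    assoc._genes = {id(g): g for g in order}
    for i, g in enumerate(order):
        if g.name.group not in ("D", "J"):
            continue
        name = format_gene_name(g.name)
        if name in overrides:
            target = by_name[overrides[name]]
            if target.name.isotype == "Delta" and mu is not None:
                target = mu
            assoc.assignments[id(g)] = target
            assoc.members.setdefault(id(target), []).append(g)
            continue
        target = None
        for j in range(i + 1, len(order)):
            other = order[j]
            if other.name.group == "V":
                break
            if other.name.group == "C":
                target = other
                break
        if target is None:
            if g.name.group == "J":
                raise ValueError(f"J gene {name} cannot be DISPERSED")
            assoc.assignments[id(g)] = DISPERSED
            continue
        if target.name.isotype == "Delta" and mu is not None:
            target = mu
        assoc.assignments[id(g)] = target
        assoc.members.setdefault(id(target), []).append(g)
    return assoc


def assign_positional_names(
    layout: LocusLayout,
    subgroups: SubgroupAssignment,
    assoc: ClusterAssociation,
    species: str = "",
) -> GeneTable:
    """Assign positional IMGT-style names to every gene of a laid-out locus.

    V genes are numbered 1..N by increasing distance from the mu D-J-C
    cluster (position 1 nearest IGHM), a single series per locus shared
    across subgroups.  Cluster D/J genes get cluster indices 1..k in 5'->3'
    order plus their cluster's tau tag; dispersed D genes get hyphen
    positions numbered in the same 3'->5' direction as the V genes.  Tau
    constant genes are numbered 1..n in 5'->3' order.  On locus B every name
    carries ``duplicated=True``.

    ``subgroups.labels`` is keyed by each V gene's current symbol (or by a
    per-gene key assigned upstream); a missing V subgroup raises.
    """
    dup = layout.locus.locus_id == "B"
    order = layout.order
    rows = []

    def key_of(g: GermlineGene) -> str:
        return format_gene_name(g.name)

    # --- constant genes: tau series numbered 5'->3'
    new_names: Dict[int, GeneName] = {}
    tau_counter = 0
    for g in order:
        if g.name.group != "C":
            continue
        if g.name.isotype == "T":
            tau_counter += 1
            new_names[id(g)] = GeneName(
                group="C", isotype="T", subgroup=tau_counter, duplicated=dup
            )
        else:
            new_names[id(g)] = replace(g.name, duplicated=dup)

    # --- V genes: position 1 = nearest the mu cluster, increasing 3'->5'
    v_genes = [g for g in order if g.name.group == "V"]
    for pos, g in enumerate(reversed(v_genes), start=1):
        sub = subgroups.labels.get(key_of(g))
        if sub is None:
            raise ValueError(f"V gene {key_of(g)} has no subgroup assignment")
        new_names[id(g)] = GeneName(group="V", subgroup=sub, duplicated=dup, position=pos)

    # --- dispersed D genes: hyphen positions in the same 3'->5' direction
    dispersed = [g for g in order if g.name.group == "D" and assoc.cluster_of(g) == DISPERSED]
    for pos, g in enumerate(reversed(dispersed), start=1):
        new_names[id(g)] = GeneName(group="D", position=pos, duplicated=dup)

    # --- cluster D/J genes: per-cluster 5'->3' indices + tau tag
    for c_id, members in assoc.members.items():
        c_gene = assoc._genes[c_id]
        tag = new_names[id(c_gene)].subgroup if c_gene.name.isotype == "T" else None
        d_i = j_i = 0
        for g in members:
            if g.name.group == "D":
                d_i += 1
                idx = d_i
            else:
                j_i += 1
                idx = j_i
            if g.name.group == "J" and assoc.cluster_of(g) == DISPERSED:
                raise ValueError("J gene cannot be dispersed")
            new_names[id(g)] = GeneName(
                group=g.name.group, cluster_index=idx, c_tag=tag, duplicated=dup
            )

    for g in order:
        gn = new_names[id(g)]
        rows.append(
            {
                "name": format_gene_name(gn),
                "species": species or layout.locus.species,
                "locus_id": layout.locus.locus_id,
                "chromosome": layout.locus.chromosome,
                "start": g.start,
                "stop": g.stop,
                "polarity": g.polarity,
                "subgroup": gn.subgroup if gn.group == "V" else "",
                "allele": 1,
                "functionality": (g.best_functionality() or "unstated"),
            }
        )
    return GeneTable(pd.DataFrame(rows))


_SO_TYPES = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
    "C": "C_gene_segment",
}


def write_gff3(layout: LocusLayout, table: GeneTable, handle) -> None:
    """Emit the named locus as GFF3 (1-based; strand = orientation x polarity)."""
    handle.write("##gff-version 3\n")
    locus = layout.locus
    fwd = locus.orientation == "FWD"
    by_coord = {(g.start, g.stop): g for g in layout.order}
    from .igmodel import parse_gene_name

    for _, row in table.df.drop_duplicates("name").iterrows():
        g = by_coord[(int(row["start"]), int(row["stop"]))]
        same = g.polarity == "same"
        strand = "+" if (fwd == same) else "-"
        group = parse_gene_name(row["name"]).group
        handle.write(
            "\t".join(
                [
                    str(locus.chromosome),
                    "salmonigh",
                    _SO_TYPES[group],
                    str(g.start),
                    str(g.stop),
                    ".",
                    strand,
                    ".",
                    f"ID={row['name']};locus_id={locus.locus_id}",
                ]
            )
            + "\n"
        )


def format_locus_map(table: GeneTable) -> str:
    """One-line-per-gene text map of a named locus (5'->3' as tabled)."""
    lines = []
    for _, row in table.df.drop_duplicates("name").iterrows():
        marker = "<" if row["polarity"] == "opposite" else ">"
        lines.append(
            f"{marker} {row['name']:<14} {row['functionality']:<8} "
            f"{row['start']}..{row['stop']}"
        )
    return "\n".join(lines)
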