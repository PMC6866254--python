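"""Reference directory sets for repertoire annotation.

A reference directory is the filtered collection of germline alleles a
repertoire annotator aligns reads against.  Two set types are supported,
mirroring standard practice for V-gene directories:

* ``F_ORF`` -- all functional and ORF alleles;
* ``F_ORF_INFRAME_P`` -- additionally pseudogene alleles whose V-REGION
  reading frame is open ("in-frame P"); out-of-frame pseudogene alleles are
  always excluded.

Functionality is honored per allele: a gene carrying both an F and a P
allele contributes its F allele to either set regardless of the P sibling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .igmodel import (
    AlleleRef,
    GeneTable,
    format_gene_name,
    parse_allele_ref,
    parse_gene_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DirectorySetSpec",
    "DirectoryEntry",
    "ReferenceDirectory",
    "build_directory",
    "write_directory_fasta",
    "read_directory_fasta",
    "summarize_gene_table",
    "register_allele",
]

SET_TYPES = ("F_ORF", "F_ORF_INFRAME_P")
_FUNC_ORDER = {"F": 0, "ORF": 1, "P": 2}


@dataclass(frozen=True)
class DirectorySetSpec:
    """Which alleles a directory admits."""

    set_type: str = "F_ORF_INFRAME_P"
    species: str = ""
    group: str = "V"
    one_allele_per_gene: bool = False

    def __post_init__(self) -> None:
        if self.set_type not in SET_TYPES:
            raise ValueError(f"set_type must be one of {SET_TYPES}")

    def admits(self, functionality: str, in_frame: bool) -> bool:
        if functionality in ("F", "ORF"):
            return True
        if functionality == "P" and self.set_type == "F_ORF_INFRAME_P":
            return bool(in_frame)
        return False


@dataclass
class DirectoryEntry:
    ref: AlleleRef
    functionality: str
    locus_id: str
    sequence: Optional[str] = None
    region_label: str = "V-REGION"
    species: str = ""


@dataclass
class ReferenceDirectory:
    """A serializable set of reference alleles (unique by allele reference)."""

    spec: DirectorySetSpec
    entries: List[DirectoryEntry] = field(default_factory=list)
    release_tag: str = ""
    audit_log: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [str(e.ref) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("directory entries must be unique by allele reference")

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceDirectory):
            return NotImplemented
        a = [(str(e.ref), e.functionality, e.locus_id, e.sequence) for e in self.entries]
        b = [(str(e.ref), e.functionality, e.locus_id, e.sequence) for e in other.entries]
        return a == b and self.spec == other.spec

    def allele_refs(self) -> List[str]:
        return [str(e.ref) for e in self.entries]

    def subset(self, group: str) -> "ReferenceDirectory":
        return ReferenceDirectory(
            spec=self.spec,
            entries=[e for e in self.entries if e.ref.gene.group == group],
            release_tag=self.release_tag,
        )


def build_directory(table: GeneTable, spec: DirectorySetSpec) -> ReferenceDirectory:
    """Filter a validated gene table into a reference directory.

    Includes every allele with functionality F or ORF, plus in-frame P
    alleles when the set type asks for them.  With ``one_allele_per_gene``,
    each gene contributes the lowest-numbered allele among those sharing the
    gene's best admitted functionality.
    """
    if not table.validated:
        raise ValueError("gene table must be validated before building a directory")
    df = table.df
    if "in_frame" not in df.columns:
        df = df.assign(in_frame=True)
    entries: List[DirectoryEntry] = []
    for name, sub in df.groupby("name", sort=False):
        gn = parse_gene_name(name)
        if gn.group != spec.group:
            continue
        admitted = [
            row
            for _, row in sub.iterrows()
            if row["functionality"] in ("F", "ORF", "P")
            and spec.admits(row["functionality"], bool(row.get("in_frame", True)))
        ]
        if not admitted:
            continue
        if spec.one_allele_per_gene:
            best = min(_FUNC_ORDER[r["functionality"]] for r in admitted)
            admitted = [
                min(
                    (r for r in admitted if _FUNC_ORDER[r["functionality"]] == best),
                    key=lambda r: int(r["allele"]),
                )
            ]
        for row in admitted:
            seq = row.get("sequence")
            entries.append(
                DirectoryEntry(
                    ref=AlleleRef(gn, int(row["allele"])),
                    functionality=row["functionality"],
                    locus_id=row["locus_id"],
                    sequence=seq if isinstance(seq, str) and seq else None,
                    species=row.get("species", spec.species),
                )
            )
    return ReferenceDirectory(spec=spec, entries=entries)


_HEADER_FIELDS = ("allele", "species", "functionality", "locus_id", "region")


def write_directory_fasta(directory: ReferenceDirectory, handle) -> None:
    """Serialize a directory to FASTA with pipe-delimited headers.

    Header fields, in order: allele reference (``GENE*NN``) | species |
    functionality | locus_id | region label.
    """
    for e in directory.entries:
        if not e.sequence:
            raise ValueError(f"entry {e.ref} has no sequence; cannot serialize")
        header = "|".join(
            [str(e.ref), e.species or directory.spec.species, e.functionality, e.locus_id, e.region_label]
        )
        handle.write(f">{header}\n{e.sequence}\n")


def read_directory_fasta(handle, spec: Optional[DirectorySetSpec] = None) -> ReferenceDirectory:
    """Parse a pipe-delimited directory FASTA (inverse of the writer)."""
    from Bio import SeqIO

    entries = []
    species = ""
    for rec in SeqIO.parse(handle, "fasta"):
        fields = rec.description.split("|")
        if len(fields) < len(_HEADER_FIELDS):
            missing = len(fields) + 1
            raise ValueError(
                f"malformed directory header {rec.description!r}: missing field "
                f"{missing} ({_HEADER_FIELDS[len(fields)]})"
            )
        allele_s, species, functionality, locus_id, region = fields[:5]
        entries.append(
            DirectoryEntry(
                ref=parse_allele_ref(allele_s),
                functionality=functionality,
                locus_id=locus_id,
                sequence=str(rec.seq).upper(),
                region_label=region,
                species=species,
            )
        )
    spec = spec or DirectorySetSpec(species=species)
    return ReferenceDirectory(spec=spec, entries=entries)


def summarize_gene_table(table: GeneTable, group_by: str, unit: str = "gene") -> pd.DataFrame:
    """Contingency counts of a gene table with marginals.

    ``group_by`` is ``"subgroup"``, ``"locus"`` or ``"functionality"`` (rows;
    functionality always forms the columns unless it is the grouping key, in
    which case locus does).  ``unit="gene"`` counts each gene once under its
    best functionality (F > ORF > P); ``unit="allele"`` counts every allele
    row.  The returned frame carries a ``Total`` row and column.
    """
    if group_by not in ("subgroup", "locus", "functionality"):
        raise ValueError(f"unknown group_by key {group_by!r}")
    if unit not in ("gene", "allele"):
        raise ValueError("unit must be 'gene' or 'allele'")
    df = table.df[table.df["functionality"].isin(("F", "ORF", "P"))].copy()
    if unit == "gene":
        df["_rank"] = df["functionality"].map(_FUNC_ORDER)
        df = df.sort_values("_rank").drop_duplicates("name", keep="first")
    rows_key = {"subgroup": "subgroup", "locus": "locus_id", "functionality": "functionality"}[
        group_by
    ]
    cols_key = "functionality" if group_by != "functionality" else "locus_id"
    pivot = pd.crosstab(df[rows_key], df[cols_key], margins=True, margins_name="Total")
    return pivot


def summarize_dual_count(table: GeneTable) -> pd.DataFrame:
    """Census-style presentation: genes with mixed-functionality alleles are
    printed in both classes as "(+n)" annotations rather than once under
    their best class."""
    df = table.df[table.df["functionality"].isin(("F", "ORF", "P"))].copy()
    per_gene = df.groupby("name").agg(
        locus_id=("locus_id", "first"),
        subgroup=("subgroup", "first"),
        funcs=("functionality", lambda s: frozenset(s)),
    )
    records = []
    for (sub, locus), grp in per_gene.groupby(["subgroup", "locus_id"]):
        rec = {"subgroup": sub, "locus_id": locus}
        for fv in ("F", "ORF", "P"):
            pure = int((grp["funcs"] == frozenset({fv})).sum())
            mixed = int((grp["funcs"].apply(lambda fs: fv in fs and len(fs) > 1)).sum())
            rec[fv] = f"{pure}(+{mixed})" if mixed else str(pure)
        rec["Total"] = len(grp)
        records.append(rec)
    return pd.DataFrame(records)


def register_allele(
    directory: ReferenceDirectory,
    seq: str,
    gene=None,
    threshold: float = 0.75,
) -> ReferenceDirectory:
    """Register a new sequence into a directory (returns an updated copy).

    Identical to an existing allele -> no-op (reported in the audit log).
    Differing from all alleles of an existing gene (given or best-matching at
    >= threshold identity) -> next allele number in registration order.  No
    gene given and no subgroup match -> a provisional S-named gene in a new
    subgroup slot.
    """
    from dataclasses import replace as _dc_replace

    from .igmodel import GeneName, _check_nt
    from .subgroup_classifier import assign_to_reference_subgroups, pairwise_identity

    seq = _check_nt(seq.upper())
    log = list(directory.audit_log)
    entries = list(directory.entries)

    for e in entries:
        if e.sequence == seq:
            log.append({"action": "noop", "reason": "identical", "allele": str(e.ref)})
            return ReferenceDirectory(directory.spec, entries, directory.release_tag, log)

    if gene is None:
        with_seq = [e for e in entries if e.sequence]
        if with_seq:
            best = max(with_seq, key=lambda e: pairwise_identity(seq, e.sequence))
            if pairwise_identity(seq, best.sequence) >= threshold:
                gene = best.ref.gene

    if gene is not None:
        same_gene = [e for e in entries if e.ref.gene == gene]
        next_num = max((e.ref.allele_number for e in same_gene), default=0) + 1
        ref = AlleleRef(gene, next_num)
        entries.append(
            DirectoryEntry(
                ref=ref,
                functionality="F",
                locus_id=same_gene[0].locus_id if same_gene else "A",
                sequence=seq,
                species=directory.spec.species,
            )
        )
        log.append({"action": "new_allele", "allele": str(ref)})
        return ReferenceDirectory(directory.spec, entries, directory.release_tag, log)

    # no gene and no subgroup match: provisional S-named gene in a new subgroup
    label = assign_to_reference_subgroups(seq, directory, threshold)
    if label == "NEW":
        existing = {e.ref.gene.subgroup for e in entries if e.ref.gene.group == "V"}
        subgroup = max(existing, default=0) + 1
    else:
        subgroup = label
    prov_idx = (
        max(
            (
                e.ref.gene.position
                for e in entries
                if e.ref.gene.provisional and e.ref.gene.subgroup == subgroup
            ),
            default=0,
        )
        + 1
    )
    gn = GeneName(group="V", subgroup=subgroup, position=prov_idx, provisional=True)
    ref = AlleleRef(gn, 1)
    entries.append(
        DirectoryEntry(
            ref=ref, functionality="F", locus_id="A", sequence=seq, species=directory.spec.species
        )
    )
    log.append({"action": "provisional_gene", "allele": str(ref), "subgroup": subgroup})
    return ReferenceDirectory(directory.spec, entries, directory.release_tag, log)
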