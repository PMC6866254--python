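"""Core domain types and the bidirectional grammar for salmonid IGH gene names.

Salmonid IGH loci come in duplicated pairs (locus A / locus B) produced by the
salmonid whole-genome tetraploidization; genes on locus B carry a ``D`` (for
"duplicated") marker in their symbol.  The grammar covered here:

* Variable genes: ``IGHV<subgroup>[D]-<position>`` (e.g. ``IGHV6D-76``), with
  provisional, not-yet-localized genes written ``IGHV<subgroup>[D]S<k>``.
* Diversity genes inside a D-J-C cluster: ``IGHD<k>[T<m>][D]`` where the
  unhyphenated ``<k>`` is the index within the cluster and ``T<m>`` tags the
  tau (IGHT) cluster the gene belongs to (no tag for the mu/delta cluster).
  Diversity genes dispersed among the V genes are hyphen-numbered
  ``IGHD-<p>[D]``.
* Joining genes: ``IGHJ<k>[T<m>][D]``, always cluster-associated.
* Constant genes: ``IGHM``/``IGHMD``, ``IGHD``/``IGHDD`` (the delta constant
  gene -- a bare ``IGHD`` with no digits), and the tau series
  ``IGHT<n>[D]``.

``parse_gene_name`` and ``format_gene_name`` are exact inverses on every
valid symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "GeneName",
    "AlleleRef",
    "Functionality",
    "RSSHit",
    "GermlineAllele",
    "GermlineGene",
    "LocusModel",
    "GeneTable",
    "ValidationIssue",
    "parse_gene_name",
    "format_gene_name",
    "parse_allele_ref",
    "validate_gene_table",
    "read_gene_table",
    "write_gene_table",
    "NAME_NORMALIZATIONS",
    "normalize_name",
]

GROUPS = ("V", "D", "J", "C")
ISOTYPES = ("M", "Delta", "T")
FUNCTIONALITY_VALUES = ("F", "ORF", "P")

#: Defect codes used by :class:`Functionality`.
PSEUDO_REASONS = ("STOP_CODON", "FRAMESHIFT", "NO_INIT", "TRUNCATED")
ORF_REASONS = ("RSS_DEFECT", "SPLICE_DEFECT", "CONSERVED_AA_CHANGE")

#: Printed-table typo corrections applied when loading fixtures (I/1 confusion
#: in the IGHJ series, missing hyphens, stray tokens).
NAME_NORMALIZATIONS = {
    "IGHJIT4": "IGHJ1T4",
    "IGHJIT5": "IGHJ1T5",
    "IGHJID": "IGHJ1D",
    "IGHV12D56": "IGHV12D-56",
    "IGHV12D57": "IGHV12D-57",
    "IGH IGHV10-47": "IGHV10-47",
}


def normalize_name(s: str) -> str:
    """Apply the documented typo-normalization map to a printed gene symbol."""
    return NAME_NORMALIZATIONS.get(s.strip(), s.strip())


@dataclass(frozen=True)
class GeneName:
    """Structured decomposition of a salmonid IGH gene symbol.

    ``subgroup`` holds the V subgroup for V genes and the tau series number
    for IGHT constant genes.  ``c_tag`` is the tau-cluster tag (the ``<m>``
    of ``T<m>``) for D/J genes sitting in a tau D-J-C cluster.  Exactly one
    of ``position`` (hyphen-numbered) and ``cluster_index`` (unhyphenated)
    is set for D and J genes; V genes always carry ``position``.
    """

    group: str
    isotype: Optional[str] = None
    subgroup: Optional[int] = None
    duplicated: bool = False
    position: Optional[int] = None
    c_tag: Optional[int] = None
    cluster_index: Optional[int] = None
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"invalid group {self.group!r}")
        if (self.isotype is not None) != (self.group == "C"):
            raise ValueError("isotype is set if and only if group is C")
        if self.isotype is not None and self.isotype not in ISOTYPES:
            raise ValueError(f"invalid isotype {self.isotype!r}")
        if self.c_tag is not None and self.group not in ("D", "J"):
            raise ValueError("c_tag is only valid for D and J genes")
        if self.group == "V":
            if self.position is None:
                raise ValueError("V genes always have a position")
            if self.subgroup is None:
                raise ValueError("V genes always have a subgroup")
            if self.cluster_index is not None:
                raise ValueError("V genes never have a cluster index")
        elif self.group in ("D", "J"):
            if (self.position is None) == (self.cluster_index is None):
                raise ValueError(
                    "exactly one of position/cluster_index must be set "
                    f"for {self.group} genes"
                )
            if self.group == "J" and self.position is not None and not self.provisional:
                raise ValueError("J genes are always cluster-associated")
        else:  # C
            if self.position is not None or self.cluster_index is not None:
                raise ValueError("C genes have neither position nor cluster index")
            if self.isotype == "T" and self.subgroup is None:
                raise ValueError("tau constant genes carry a series number")
            if self.isotype in ("M", "Delta") and self.subgroup is not None:
                raise ValueError("mu/delta constant genes have no series number")
        for attr in ("subgroup", "position", "c_tag", "cluster_index"):
            v = getattr(self, attr)
            if v is not None and (not isinstance(v, int) or v < 1):
                raise ValueError(f"{attr} must be a positive integer, got {v!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_gene_name(self)


# Regular expressions of the grammar, tried in order.  ``IGHD`` is the one
# ambiguous prefix: bare (or bare + ``D``) means the delta constant gene,
# digit-suffixed forms are diversity genes.
_RE_C_MU = re.compile(r"^IGHM(D?)$")
_RE_C_DELTA = re.compile(r"^IGHD(D?)$")
_RE_C_TAU = re.compile(r"^IGHT([1-9]\d*)(D?)$")
_RE_V = re.compile(r"^IGHV([1-9]\d*)(D?)-([1-9]\d*)$")
_RE_V_PROV = re.compile(r"^IGHV([1-9]\d*)(D?)S([1-9]\d*)$")
_RE_D_TAU = re.compile(r"^IGHD([1-9]\d*)T([1-9]\d*)(D?)$")
_RE_D_CLUSTER = re.compile(r"^IGHD([1-9]\d*)(D?)$")
_RE_D_DISPERSED = re.compile(r"^IGHD-([1-9]\d*)(D?)$")
_RE_D_PROV = re.compile(r"^IGHDS([1-9]\d*)(D?)$")
_RE_J_TAU = re.compile(r"^IGHJ([1-9]\d*)T([1-9]\d*)(D?)$")
_RE_J_CLUSTER = re.compile(r"^IGHJ([1-9]\d*)(D?)$")
_RE_J_PROV = re.compile(r"^IGHJS([1-9]\d*)(D?)$")


def parse_gene_name(s: str) -> GeneName:
    """Parse an IGH gene symbol into its :class:`GeneName` decomposition.

    Raises :class:`ValueError` on anything outside the grammar, naming the
    first offending token.  Input must be uppercase ASCII exactly as the
    symbols are printed.
    """
    if not s:
        raise ValueError("empty gene name")
    if s != s.upper():
        raise ValueError(f"gene names are uppercase: offending token {s!r}")
    if not s.startswith("IGH"):
        raise ValueError(f"not an IGH gene symbol: offending token {s[:4]!r}")
    body = s[3:]
    if not body:
        raise ValueError("missing group letter after 'IGH'")

    if m := _RE_C_MU.match(s):
        return GeneName(group="C", isotype="M", duplicated=bool(m.group(1)))
    if m := _RE_C_DELTA.match(s):
        return GeneName(group="C", isotype="Delta", duplicated=bool(m.group(1)))
    if m := _RE_C_TAU.match(s):
        return GeneName(
            group="C", isotype="T", subgroup=int(m.group(1)), duplicated=bool(m.group(2))
        )
    if m := _RE_V.match(s):
        return GeneName(
            group="V",
            subgroup=int(m.group(1)),
            duplicated=bool(m.group(2)),
            position=int(m.group(3)),
        )
    if m := _RE_V_PROV.match(s):
        return GeneName(
            group="V",
            subgroup=int(m.group(1)),
            duplicated=bool(m.group(2)),
            position=int(m.group(3)),
            provisional=True,
        )
    if m := _RE_D_TAU.match(s):
        return GeneName(
            group="D",
            cluster_index=int(m.group(1)),
            c_tag=int(m.group(2)),
            duplicated=bool(m.group(3)),
        )
    if m := _RE_D_DISPERSED.match(s):
        return GeneName(group="D", position=int(m.group(1)), duplicated=bool(m.group(2)))
    if m := _RE_D_PROV.match(s):
        return GeneName(
            group="D", position=int(m.group(1)), duplicated=bool(m.group(2)), provisional=True
        )
    if m := _RE_D_CLUSTER.match(s):
        return GeneName(group="D", cluster_index=int(m.group(1)), duplicated=bool(m.group(2)))
    if m := _RE_J_TAU.match(s):
        return GeneName(
            group="J",
            cluster_index=int(m.group(1)),
            c_tag=int(m.group(2)),
            duplicated=bool(m.group(3)),
        )
    if m := _RE_J_PROV.match(s):
        return GeneName(
            group="J", position=int(m.group(1)), duplicated=bool(m.group(2)), provisional=True
        )
    if m := _RE_J_CLUSTER.match(s):
        return GeneName(group="J", cluster_index=int(m.group(1)), duplicated=bool(m.group(2)))

    if body[0] not in ("V", "D", "J", "M", "T"):
        raise ValueError(f"invalid group letter: offending token {body[0]!r}")
    raise ValueError(f"unparsable gene name: offending token {s!r}")


def format_gene_name(gn: GeneName) -> str:
    """Render a :class:`GeneName` to its canonical symbol (inverse of parse)."""
    dup = "D" if gn.duplicated else ""
    if gn.group == "C":
        if gn.isotype == "M":
            return f"IGHM{dup}"
        if gn.isotype == "Delta":
            return f"IGHD{dup}"
        return f"IGHT{gn.subgroup}{dup}"
    if gn.group == "V":
        sep = "S" if gn.provisional else "-"
        return f"IGHV{gn.subgroup}{dup}{sep}{gn.position}"
    # D / J
    letter = gn.group
    if gn.provisional:
        return f"IGH{letter}S{gn.position}{dup}"
    if gn.position is not None:  # dispersed D
        return f"IGH{letter}-{gn.position}{dup}"
    tag = f"T{gn.c_tag}" if gn.c_tag is not None else ""
    return f"IGH{letter}{gn.cluster_index}{tag}{dup}"


@dataclass(frozen=True)
class AlleleRef:
    """A gene plus an allele number, rendered ``GENE*NN`` (zero-padded)."""

    gene: GeneName
    allele_number: int

    def __post_init__(self) -> None:
        if self.allele_number < 1:
            raise ValueError("allele_number must be >= 1")

    def __str__(self) -> str:
        return f"{format_gene_name(self.gene)}*{self.allele_number:02d}"


def parse_allele_ref(s: str) -> AlleleRef:
    """Parse ``GENE*NN`` into an :class:`AlleleRef`."""
    if "*" not in s:
        raise ValueError(f"allele reference lacks '*': {s!r}")
    gene_s, _, num_s = s.partition("*")
    if not num_s.isdigit():
        raise ValueError(f"invalid allele number: {num_s!r}")
    return AlleleRef(gene=parse_gene_name(gene_s), allele_number=int(num_s))


@dataclass(frozen=True)
class Functionality:
    """IMGT functionality call: F, ORF, or P, with defect codes.

    ``in_frame`` is meaningful for pseudogenes only: True when the V-REGION
    reading frame is open end to end (stop codon or flanking defect only,
    no frameshift).
    """

    value: str
    in_frame: bool = True
    reasons: tuple = ()

    def __post_init__(self) -> None:
        if self.value not in FUNCTIONALITY_VALUES:
            raise ValueError(f"functionality must be one of {FUNCTIONALITY_VALUES}")
        if self.value == "F" and self.reasons:
            raise ValueError("functional alleles carry no defect reasons")
        if self.value == "P" and not any(r in PSEUDO_REASONS for r in self.reasons):
            if not self.reasons:
                raise ValueError("pseudogene calls require at least one defect reason")
        for r in self.reasons:
            if r not in PSEUDO_REASONS + ORF_REASONS:
                raise ValueError(f"unknown defect code {r!r}")


@dataclass(frozen=True)
class RSSHit:
    """A recombination-signal-sequence hit: heptamer + 12/23 spacer + nonamer."""

    heptamer: str
    spacer_length: int
    nonamer: str
    score: int
    offset: int

    def __post_init__(self) -> None:
        if self.spacer_length not in range(11, 25):
            raise ValueError("spacer length must be near 12 or 23")
        if self.score < 0:
            raise ValueError("score is a mismatch count, >= 0")


_NT = set("ACGTN")


def _check_nt(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"empty {what}")
    if set(seq) - _NT:
        bad = sorted(set(seq) - _NT)
        raise ValueError(f"{what} contains non-nucleotide characters {bad}")
    return seq


@dataclass
class GermlineAllele:
    """One germline allele with its core region sequence and functionality.

    ``v_region_nt`` holds the V-REGION for V genes and the analogous
    D-/J-/C-REGION for the other groups.  ``flank_3p`` (and ``flank_5p`` for
    the upstream flank of D genes) optionally carry genomic context used for
    RSS detection.
    """

    ref: AlleleRef
    functionality: Optional[Functionality] = None
    v_region_nt: Optional[str] = None
    leader_nt: Optional[str] = None
    rss: Optional[RSSHit] = None
    flank_3p: Optional[str] = None
    flank_5p: Optional[str] = None
    splice_defect: bool = False

    def __post_init__(self) -> None:
        if self.v_region_nt is not None:
            _check_nt(self.v_region_nt, "region sequence")


@dataclass
class GermlineGene:
    """A located germline gene with one or more alleles."""

    name: GeneName
    locus_id: str
    chromosome: str
    start: int
    stop: int
    polarity: str = "same"
    alleles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.locus_id not in ("A", "B"):
            raise ValueError("locus_id must be 'A' or 'B'")
        if self.start == self.stop:
            raise ValueError("degenerate interval: start == stop")
        if self.start > self.stop:
            # Reversed coordinate pair encodes opposite polarity.
            self.start, self.stop = self.stop, self.start
            self.polarity = "opposite"
        if self.polarity not in ("same", "opposite"):
            raise ValueError("polarity must be 'same' or 'opposite'")
        nums = [a.ref.allele_number for a in self.alleles]
        if len(nums) != len(set(nums)):
            raise ValueError("alleles must carry distinct allele numbers")

    @property
    def midpoint(self) -> float:
        return (self.start + self.stop) / 2.0

    def best_functionality(self) -> Optional[str]:
        """Best functionality over alleles (F > ORF > P)."""
        order = {"F": 0, "ORF": 1, "P": 2}
        vals = [a.functionality.value for a in self.alleles if a.functionality]
        return min(vals, key=order.__getitem__) if vals else None


@dataclass
class LocusModel:
    """One IGH locus: orientation, span and its gene content."""

    species: str
    locus_id: str
    chromosome: str
    orientation: str
    span: tuple
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in ("FWD", "REV"):
            raise ValueError("orientation must be FWD or REV")
        lo, hi = self.span
        if lo >= hi:
            raise ValueError("span must be a non-empty interval")
        for g in self.genes:
            if g.start < lo or g.stop > hi:
                raise ValueError(f"gene {format_gene_name(g.name)} outside locus span")


# ---------------------------------------------------------------------------
# GeneTable: one row per allele, pandas-backed.

GENE_TABLE_COLUMNS = [
    "name",
    "species",
    "locus_id",
    "chromosome",
    "start",
    "stop",
    "polarity",
    "subgroup",
    "allele",
    "functionality",
]
OPTIONAL_COLUMNS = ["in_frame", "sequence"]


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    message: str


class GeneTable:
    """Ordered collection of germline gene/allele rows for one or two loci.

    Thin wrapper around a :class:`pandas.DataFrame` with one row per allele
    (columns ``name, species, locus_id, chromosome, start, stop, polarity,
    subgroup, allele, functionality`` plus optional ``in_frame, sequence``).
    A blank functionality cell is preserved as the string ``"unstated"``.
    """

    def __init__(self, df):
        import pandas as pd

        missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        self.df = df.reset_index(drop=True)
        self._validated = False

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneTable) and self.df.equals(other.df)

    @property
    def validated(self) -> bool:
        return self._validated

    def gene_names(self) -> list:
        return list(dict.fromkeys(self.df["name"]))

    def genes(self) -> list:
        """Materialize :class:`GermlineGene` objects (one per distinct name)."""
        out = []
        for name, sub in self.df.groupby("name", sort=False):
            first = sub.iloc[0]
            alleles = []
            for _, row in sub.iterrows():
                func = None
                fval = row["functionality"]
                if fval in FUNCTIONALITY_VALUES:
                    in_frame = bool(row.get("in_frame", True))
                    reasons = ()
                    if fval == "P":
                        reasons = ("STOP_CODON",) if in_frame else ("FRAMESHIFT",)
                    elif fval == "ORF":
                        reasons = ("RSS_DEFECT",)
                    func = Functionality(fval, in_frame=in_frame, reasons=reasons)
                seq = row.get("sequence")
                alleles.append(
                    GermlineAllele(
                        ref=AlleleRef(parse_gene_name(name), int(row["allele"])),
                        functionality=func,
                        v_region_nt=seq if isinstance(seq, str) and seq else None,
                    )
                )
            out.append(
                GermlineGene(
                    name=parse_gene_name(name),
                    locus_id=first["locus_id"],
                    chromosome=str(first["chromosome"]),
                    start=int(first["start"]),
                    stop=int(first["stop"]),
                    polarity=first["polarity"],
                    alleles=alleles,
                )
            )
        return out


def validate_gene_table(table: GeneTable) -> list:
    """Validate a gene table row by row.

    Returns a list of :class:`ValidationIssue`; the table is accepted (its
    ``validated`` flag set) iff the list is empty.  Checked per row: the name
    parses, functionality is F/ORF/P or blank ("unstated"), the coordinate
    interval is non-degenerate, and the subgroup column matches the name's
    subgroup field for V genes.
    """
    issues = []
    for i, row in table.df.iterrows():
        try:
            gn = parse_gene_name(str(row["name"]))
        except ValueError as e:
            issues.append(ValidationIssue(i, f"unparsable name: {e}"))
            gn = None
        fval = row["functionality"]
        if fval not in FUNCTIONALITY_VALUES and fval != "unstated":
            issues.append(ValidationIssue(i, f"functionality outside F/ORF/P/blank: {fval!r}"))
        if int(row["start"]) == int(row["stop"]):
            issues.append(ValidationIssue(i, "zero-length interval"))
        if gn is not None and gn.group == "V":
            sub = row["subgroup"]
            if sub not in ("", None) and int(sub) != gn.subgroup:
                issues.append(
                    ValidationIssue(i, f"subgroup column {sub} inconsistent with name")
                )
    if not issues:
        table._validated = True
    return issues


def read_gene_table(path) -> GeneTable:
    """Read a gene-table TSV ('#' comments, UTF-8).

    Printed typos are normalized via :data:`NAME_NORMALIZATIONS`; a reversed
    coordinate pair (start > stop) is normalized to (min, max) with
    ``polarity='opposite'``; blank functionality becomes ``"unstated"``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    df["name"] = df["name"].map(normalize_name)
    for col in ("start", "stop"):
        df[col] = df[col].astype(int)
    swap = df["start"] > df["stop"]
    if "polarity" not in df.columns:
        df["polarity"] = "same"
    df.loc[df["polarity"] == "", "polarity"] = "same"
    df.loc[swap, "polarity"] = "opposite"
    df.loc[swap, ["start", "stop"]] = df.loc[swap, ["stop", "start"]].values
    df.loc[df["functionality"] == "", "functionality"] = "unstated"
    if "allele" in df.columns:
        df["allele"] = df["allele"].replace("", "1").astype(int)
    else:
        df["allele"] = 1
    if "in_frame" in df.columns:
        df["in_frame"] = df["in_frame"].map({"1": True, "0": False, "": True, "True": True, "False": False})
    return GeneTable(df)


def write_gene_table(table: GeneTable, path) -> None:
    cols = GENE_TABLE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.df.columns]
    table.df.to_csv(path, sep="\t", index=False, columns=cols)
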