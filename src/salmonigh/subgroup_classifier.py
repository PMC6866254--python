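"""Sequence-level IGHV classification.

Implements the 75%-identity subgroup rule used for salmonid IGHV genes:
pairwise V-REGION nucleotide identity from a global alignment, single-linkage
clustering of genes at a configurable threshold (default 0.75), functionality
calling (F / ORF / P with defect codes), recombination-signal-sequence (RSS)
detection, and IMGT-style gapping of translated V regions onto the unique
numbering (positions 1-104, CDR1 in 27-38, CDR2 in 56-65, anchors
1st-CYS 23 / conserved-TRP 41 / hydrophobic 89 / 2nd-CYS 104).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .igmodel import (
    Functionality,
    GermlineAllele,
    GermlineGene,
    RSSHit,
    _check_nt,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IdentityMatrix",
    "SubgroupAssignment",
    "GappedVRegion",
    "pairwise_identity",
    "identity_matrix",
    "cluster_subgroups",
    "assign_to_reference_subgroups",
    "classify_functionality",
    "find_rss",
    "gap_v_region",
    "translate",
]

RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"
#: Hydrophobic residues accepted at IMGT position 89.
HYDROPHOBIC = set("AVILMFWY")

_CODON_TABLE = None


def translate(nt: str) -> str:
    """Translate a nucleotide string in frame 0 ('*' for stops, trailing
    partial codon dropped)."""
    from Bio.Seq import Seq

    trimmed = nt[: len(nt) - len(nt) % 3]
    return str(Seq(trimmed).translate())


def _aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -4.0
    a.extend_gap_score = -1.0
    # terminal gaps are free: identity is computed over the aligned core
    try:
        a.open_end_insertion_score = 0.0
        a.extend_end_insertion_score = 0.0
        a.open_end_deletion_score = 0.0
        a.extend_end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        a.target_end_open_gap_score = 0.0
        a.target_end_extend_gap_score = 0.0
        a.query_end_open_gap_score = 0.0
        a.query_end_extend_gap_score = 0.0
    return a


def pairwise_identity(a: str, b: str, min_length: int = 30) -> float:
    """Fraction of identical columns in a global alignment of two V regions.

    Affine-gap global alignment (match +1, mismatch 0, gap open -4 /
    extend -1, free terminal gaps); identity is identical columns divided by
    aligned columns after stripping terminal-gap columns.  Symmetric.
    """
    a = _check_nt(a.upper())
    b = _check_nt(b.upper())
    if len(a) < min_length or len(b) < min_length:
        raise ValueError(f"sequences must be >= {min_length} nt")
    aln = _aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # strip terminal-gap columns
    start = 0
    end = len(s1)
    while s1[start] == "-" or s2[start] == "-":
        start += 1
    while s1[end - 1] == "-" or s2[end - 1] == "-":
        end -= 1
    cols = end - start
    ident = sum(1 for x, y in zip(s1[start:end], s2[start:end]) if x == y and x != "-")
    return ident / cols if cols else 0.0


@dataclass
class IdentityMatrix:
    """Symmetric matrix of pairwise identity fractions, diagonal exactly 1."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match the label count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("identity matrix diagonal must be 1")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("identities must lie in [0, 1]")
        self.values = v


def identity_matrix(seqs: Union[Dict[str, str], Sequence[Tuple[str, str]]]) -> IdentityMatrix:
    """Compute the all-pairs identity matrix for a set of labeled sequences."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    labels = [k for k, _ in items]
    n = len(labels)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(items[i][1], items[j][1])
    return IdentityMatrix(labels, m)


@dataclass
class SubgroupAssignment:
    """Mapping sequence ID -> subgroup label (consecutive positive integers)."""

    labels: Dict[str, int]
    threshold: float = 0.75

    @property
    def n_subgroups(self) -> int:
        return len(set(self.labels.values()))


def cluster_subgroups(matrix: IdentityMatrix, threshold: float = 0.75) -> SubgroupAssignment:
    """Single-linkage subgroup clustering at an identity threshold.

    Subgroups are the connected components of the graph with an edge wherever
    identity >= threshold.  Component labels are consecutive integers assigned
    in ascending order of each component's lexicographically smallest member.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = (matrix.values >= threshold).astype(np.int8)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    smallest: Dict[int, str] = {}
    for lbl, c in zip(matrix.labels, comp):
        if c not in smallest or lbl < smallest[c]:
            smallest[c] = lbl
    order = sorted(smallest, key=smallest.__getitem__)
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return SubgroupAssignment(
        {lbl: relabel[c] for lbl, c in zip(matrix.labels, comp)}, threshold=threshold
    )


def assign_to_reference_subgroups(seq: str, directory, threshold: float = 0.75):
    """Assign a V region to a labeled reference subgroup, or ``"NEW"``.

    Returns the subgroup of the highest-identity directory allele when that
    identity reaches the threshold; ties on identity are broken toward the
    lower subgroup number (and logged).
    """
    entries = [e for e in directory.entries if e.sequence]
    if not entries:
        raise ValueError("empty reference directory")
    best = -1.0
    hits: List[int] = []
    for e in entries:
        ident = pairwise_identity(seq, e.sequence)
        if ident > best + 1e-12:
            best, hits = ident, [e.ref.gene.subgroup]
        elif abs(ident - best) <= 1e-12:
            hits.append(e.ref.gene.subgroup)
    if best < threshold:
        return "NEW"
    subgroups = sorted(set(hits))
    if len(subgroups) > 1:
        logger.info(
            "subgroup tie at identity %.3f between %s; choosing %s",
            best, subgroups, subgroups[0],
        )
    return subgroups[0]


def find_rss(
    flank: str, expected_spacer: int, max_mismatch: int = 2
) -> Optional[RSSHit]:
    """Scan a flank for a heptamer/spacer/nonamer recombination signal.

    The heptamer consensus is CACAGTG with the first three bases required
    exact; the nonamer consensus ACAAAAACC is sought at ``expected_spacer``
    +/- 1 nt.  Returns the lowest-total-mismatch hit with each element within
    ``max_mismatch``, or None.  V genes use a 23-spacer, D genes a 12-spacer
    on both flanks, J genes a 23-spacer (upstream).
    """
    if expected_spacer not in (12, 23):
        raise ValueError("expected_spacer must be 12 or 23")
    flank = _check_nt(flank.upper(), "flank")
    min_len = 7 + (expected_spacer - 1) + 9
    if len(flank) < min_len:
        raise ValueError(f"flank shorter than heptamer+spacer+nonamer ({min_len} nt)")
    best: Optional[RSSHit] = None
    for i in range(len(flank) - 7 + 1):
        if flank[i : i + 3] != "CAC":
            continue
        hept = flank[i : i + 7]
        h_mm = sum(1 for x, y in zip(hept[3:], RSS_HEPTAMER[3:]) if x != y)
        if h_mm > max_mismatch:
            continue
        for spacer in (expected_spacer - 1, expected_spacer, expected_spacer + 1):
            j = i + 7 + spacer
            non = flank[j : j + 9]
            if len(non) < 9:
                continue
            n_mm = sum(1 for x, y in zip(non, RSS_NONAMER) if x != y)
            if n_mm > max_mismatch:
                continue
            hit = RSSHit(hept, spacer, non, h_mm + n_mm, i)
            key = (hit.score, abs(spacer - expected_spacer), i)
            if best is None or key < (
                best.score, abs(best.spacer_length - expected_spacer), best.offset
            ):
                best = hit
    return best


@dataclass
class GappedVRegion:
    """A translated V region laid out on IMGT unique-numbering positions 1-104."""

    gapped_aa: str
    anchors: Dict[str, int] = field(
        default_factory=lambda: {
            "1st-CYS": 23,
            "CONSERVED-TRP": 41,
            "HYDROPHOBIC-89": 89,
            "2nd-CYS": 104,
        }
    )
    cdr1_length: int = 0
    cdr2_length: int = 0

    def residue(self, position: int) -> str:
        """Residue (or '.') at a 1-based IMGT position."""
        return self.gapped_aa[position - 1]


def _gap_loop(residues: str, slots: int) -> str:
    """Lay a CDR loop into its IMGT window: gaps at the loop top, filling the
    middle positions outward (first half left-aligned, second half
    right-aligned)."""
    if len(residues) > slots:
        raise ValueError(f"loop of {len(residues)} aa exceeds {slots} IMGT positions")
    left = (len(residues) + 1) // 2
    return residues[:left] + "." * (slots - len(residues)) + residues[left:]


def gap_v_region(aa: str) -> GappedVRegion:
    """Gap a translated V-REGION onto IMGT positions 1-104.

    The framework regions are filled 1:1 (FR1 positions 1-26, FR2 39-55,
    FR3 66-104); CDR1 occupies 27-38 and CDR2 56-65 with gaps inserted at
    the loop top.  Anchors are located by motif search: 1st-CYS must sit at
    position 23 (residue index 22) and 2nd-CYS at 104 (the final residue);
    the conserved TRP is sought at the FR2 offset compatible with a CDR1 of
    0-12 aa.  Raises when either CYS anchor cannot be placed.
    """
    aa = aa.upper()
    if "*" in aa:
        raise ValueError("V region translation contains a stop character")
    L = len(aa)
    loop_total = L - 82
    if loop_total < 0 or loop_total > 22:
        raise ValueError(f"V region of {L} aa cannot be laid out on positions 1-104")
    if L < 23 or aa[22] != "C":
        raise ValueError("1st-CYS anchor (position 23) cannot be placed")
    if aa[-1] != "C":
        raise ValueError("2nd-CYS anchor (position 104) cannot be placed")
    cdr1_len = None
    for idx in range(28, 28 + 13):  # candidate conserved-TRP indices (CDR1 len 0..12)
        if idx < L and aa[idx] == "W":
            c1 = idx - 28
            c2 = loop_total - c1
            if 0 <= c2 <= 10:
                cdr1_len = c1
                break
    if cdr1_len is None:
        # TRP not found: fall back to length arithmetic (anchor reported absent)
        cdr1_len = min(12, loop_total)
    cdr2_len = loop_total - cdr1_len
    if not (0 <= cdr2_len <= 10):
        raise ValueError("CDR lengths incompatible with IMGT windows (max 12 + 10)")
    fr1 = aa[:26]
    cdr1 = aa[26 : 26 + cdr1_len]
    fr2 = aa[26 + cdr1_len : 26 + cdr1_len + 17]
    cdr2 = aa[43 + cdr1_len : 43 + cdr1_len + cdr2_len]
    fr3 = aa[43 + cdr1_len + cdr2_len :]
    gapped = fr1 + _gap_loop(cdr1, 12) + fr2 + _gap_loop(cdr2, 10) + fr3
    assert len(gapped) == 104
    return GappedVRegion(gapped_aa=gapped, cdr1_length=cdr1_len, cdr2_length=cdr2_len)


def classify_functionality(
    gene: GermlineGene,
    allele: GermlineAllele,
    *,
    min_v_length: int = 270,
    strict_flank_mode: bool = False,
) -> Functionality:
    """Call IMGT functionality (F / ORF / P) for a germline V allele.

    Pseudogene (P) with reason STOP_CODON / FRAMESHIFT / NO_INIT / TRUNCATED
    when the V-REGION frame contains a stop, its length is not a codon
    multiple, the leader lacks an initiation codon, or the region is shorter
    than ``min_v_length``.  ORF with reason RSS_DEFECT / SPLICE_DEFECT /
    CONSERVED_AA_CHANGE when the frame is open but a flanking element or an
    anchor residue (positions 23 / 41 / 89 / 104) is defective.  F otherwise.

    ``in_frame`` on P is True iff no frameshift.  ``strict_flank_mode``
    downgrades flanking-element defects on otherwise-open frames from ORF to
    in-frame P (the alternative reading in which RS/leader defects are
    grouped with pseudogenes).
    """
    if allele.v_region_nt is None:
        raise ValueError("allele has no V-REGION sequence")
    v = allele.v_region_nt.upper()
    p_reasons: List[str] = []
    if len(v) % 3 != 0:
        p_reasons.append("FRAMESHIFT")
    if len(v) < min_v_length:
        p_reasons.append("TRUNCATED")
    aa = translate(v)
    if "*" in aa:
        p_reasons.append("STOP_CODON")
    if allele.leader_nt is not None and not allele.leader_nt.upper().startswith("ATG"):
        p_reasons.append("NO_INIT")
    if p_reasons:
        return Functionality("P", in_frame="FRAMESHIFT" not in p_reasons, reasons=tuple(p_reasons))

    orf_reasons: List[str] = []
    if allele.flank_3p is not None:
        spacer = 23 if gene.name.group == "V" else 12
        if find_rss(allele.flank_3p, spacer) is None:
            orf_reasons.append("RSS_DEFECT")
    if allele.splice_defect:
        orf_reasons.append("SPLICE_DEFECT")
    if gene.name.group == "V":
        try:
            gapped = gap_v_region(aa)
            ok = (
                gapped.residue(23) == "C"
                and gapped.residue(41) == "W"
                and gapped.residue(89) in HYDROPHOBIC
                and gapped.residue(104) == "C"
            )
        except ValueError:
            ok = False
        if not ok:
            orf_reasons.append("CONSERVED_AA_CHANGE")
    if orf_reasons:
        if strict_flank_mode:
            return Functionality("P", in_frame=True, reasons=tuple(orf_reasons))
        return Functionality("ORF", reasons=tuple(orf_reasons))
    return Functionality("F")
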