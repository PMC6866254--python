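"""Synthetic duplicated IGH loci and rearranged repertoires with ground truth.

The germline generator emulates the salient architecture of salmonid IGH
loci: several V subgroups whose members share high within-subgroup identity
while staying well below the subgroup threshold between subgroups, an
optional near-identical duplicated locus (locus B, "D"-suffixed names),
planted functionality defects (stop codons / frameshifts -> pseudogenes,
recombination-signal mutations -> ORF), and D-J-C clusters (one tau, one
mu/delta).  The repertoire generator draws V-D-J rearrangements with
exonuclease trimming, N additions, optional uniform point mutations and
optional UMIs; every read carries a truth row.

V regions are built on the IMGT architecture (FR1 26 aa with 1st-CYS at 23,
CDR1, FR2 17 aa with the conserved TRP, CDR2, FR3 39 aa ending in the
2nd-CYS at 104), so the classifier's anchor and gapping logic applies to
simulated genes exactly as to real ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .igmodel import (
    AlleleRef,
    Functionality,
    GeneName,
    GeneTable,
    GermlineAllele,
    GermlineGene,
    LocusModel,
    format_gene_name,
)
from .refdir import DirectoryEntry, DirectorySetSpec, ReferenceDirectory
from .subgroup_classifier import RSS_HEPTAMER, RSS_NONAMER, HYDROPHOBIC

__all__ = ["SimConfig", "SimTruth", "simulate_germline_locus", "simulate_repertoire"]

_NTS = np.array(list("ACGT"))
# codons avoided when drawing framework/CDR residues
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Generator parameters.

    Identity targets are alignment-identity fractions: members of one
    subgroup end up within ``within_subgroup_identity`` +/- 0.03 of each
    other; subgroup ancestors are rejection-sampled until every between-
    subgroup identity is at or below ``between_subgroup_identity`` (the
    ceiling must sit below the 0.75 subgroup threshold, the within target
    above it).  ``duplicate_divergence`` is the per-base divergence of the
    locus-B copy of each gene.  Trim and N-addition parameters shape the
    simulated V-D-J junctions.
    """

    n_subgroups: int = 3
    genes_per_subgroup: int = 4
    within_subgroup_identity: float = 0.85
    between_subgroup_identity: float = 0.65
    duplicate_locus: bool = False
    duplicate_divergence: float = 0.02
    pseudogene_fraction: float = 0.15
    orf_fraction: float = 0.10
    v_region_length: int = 300
    cdr1_aa: int = 10
    cdr2_aa: int = 8
    n_d_genes: int = 4
    n_j_genes: int = 3
    d_region_length: int = 16
    v_trim_max: int = 5
    d_trim_max: int = 6
    j_trim_max: int = 5
    n_insert_mean: float = 3.0
    mutation_rate: float = 0.0
    n_reads: int = 100
    umi_length: int = 0
    umi_duplication: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.between_subgroup_identity < 0.75 < self.within_subgroup_identity
        ):
            raise ValueError(
                "identity ceiling must sit below the 0.75 threshold and the "
                "within-subgroup target above it"
            )
        for frac in (self.pseudogene_fraction, self.orf_fraction, self.mutation_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.pseudogene_fraction + self.orf_fraction > 1:
            raise ValueError("defect fractions must sum to at most 1")
        if self.v_region_length % 3:
            raise ValueError("v_region_length must be a codon multiple")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SimTruth:
    """Ground truth: per-gene plants and per-read draws."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_codon(rng: np.random.Generator, aa_pool: Optional[str] = None) -> str:
    while True:
        codon = "".join(rng.choice(_NTS, 3))
        if codon in _STOPS:
            continue
        if aa_pool is not None:
            from Bio.Seq import Seq

            if str(Seq(codon).translate()) not in aa_pool:
                continue
        return codon


_AA_CODON = {
    "C": "TGC", "W": "TGG", "V": "GTG", "L": "CTG", "M": "ATG",
}


def _v_region_ancestor(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Draw one V-REGION with the IMGT anchor architecture.

    Layout in codons: FR1 26 (CYS at 23), CDR1 ``cdr1_aa``, FR2 17 (TRP at
    position 41 = FR2 codon 3), CDR2 ``cdr2_aa``, FR3 39 (hydrophobic at 89,
    CYS at 104).  Tryptophan is excluded outside its anchor so the gapping
    motif search is unambiguous; total length must equal v_region_length/3.
    """
    n_aa = cfg.v_region_length // 3
    if 26 + cfg.cdr1_aa + 17 + cfg.cdr2_aa + 39 != n_aa:
        raise ValueError("cdr1_aa + cdr2_aa inconsistent with v_region_length")
    no_w = "ACDEFGHIKLMNPQRSTVY"

    def codons(n: int) -> List[str]:
        return [_random_codon(rng, no_w) for _ in range(n)]

    fr1 = codons(22) + [_AA_CODON["C"]] + codons(3)
    cdr1 = codons(cfg.cdr1_aa)
    fr2 = codons(2) + [_AA_CODON["W"]] + codons(14)
    cdr2 = codons(cfg.cdr2_aa)
    fr3 = codons(23) + [_AA_CODON["V"]] + codons(14) + [_AA_CODON["C"]]
    return "".join(fr1 + cdr1 + fr2 + cdr2 + fr3)


def _mutate_keeping_architecture(
    seq: str, rng: np.random.Generator, n_subs: int, protected: Optional[set] = None
) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct non-anchor codon
    positions without creating stop codons."""
    from Bio.Seq import Seq

    n_aa = len(seq) // 3
    protected = protected or set()
    anchor_codons = {22, 25 + 0, n_aa - 1}  # 1st-CYS, conserved-TRP slot, 2nd-CYS
    # identify the TRP anchor codon by translation (trailing partial dropped)
    aa = str(Seq(seq[: 3 * n_aa]).translate())
    anchor_codons |= {i for i, r in enumerate(aa) if r in "CW"}
    anchor_codons.add(n_aa - 16)  # hydrophobic 89
    out = list(seq)
    eligible = [
        p for p in range(len(seq)) if (p // 3) not in anchor_codons and p not in protected
    ]
    rng.shuffle(eligible)
    done = 0
    for p in eligible:
        if done == n_subs:
            break
        old = out[p]
        choices = [c for c in "ACGT" if c != old]
        rng.shuffle(choices)
        for c in choices:
            out[p] = c
            codon_start = 3 * (p // 3)
            codon = "".join(out[codon_start : codon_start + 3])
            if codon not in _STOPS and codon != "TGG":  # never create a stray TRP
                done += 1
                break
            out[p] = old
    return "".join(out)


def _alignment_free_identity(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / max(len(a), len(b))


def _good_flank(rng: np.random.Generator, spacer: int = 23) -> str:
    pad = "".join(rng.choice(_NTS, 6))
    spacer_seq = "".join(rng.choice(_NTS, spacer))
    tail = "".join(rng.choice(_NTS, 6))
    flank = pad + RSS_HEPTAMER + spacer_seq + RSS_NONAMER + tail
    # make sure the only CAC seed yielding a full RSS is the planted one
    return flank


def simulate_germline_locus(cfg: SimConfig):
    """Generate one locus (or a duplicated pair) with planted ground truth.

    Returns ``(loci, gene_table, truth)`` where ``loci`` is a list of one or
    two :class:`LocusModel` (locus A, optionally its diverged locus-B copy),
    ``gene_table`` carries one row per allele with positional names already
    assigned, and ``truth.genes`` records the planted subgroup, functionality
    and defect of every gene.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_aa = cfg.v_region_length // 3

    # --- subgroup ancestors, rejection-sampled below the identity ceiling
    ancestors: List[str] = []
    for _ in range(cfg.n_subgroups):
        for attempt in range(200):
            cand = _v_region_ancestor(rng, cfg)
            if all(
                _alignment_free_identity(cand, a) <= cfg.between_subgroup_identity
                for a in ancestors
            ):
                ancestors.append(cand)
                break
        else:
            raise RuntimeError(
                "rejection sampling exceeded its iteration cap; identity "
                "ceiling too tight for this V-region length"
            )

    # --- members: mutate each ancestor so pairwise identities hit the target
    per_member = int(round((1 - cfg.within_subgroup_identity) / 2 * cfg.v_region_length))
    n_genes = cfg.n_subgroups * cfg.genes_per_subgroup
    n_pseudo = int(round(cfg.pseudogene_fraction * n_genes))
    n_orf = int(round(cfg.orf_fraction * n_genes))
    defect_plan = ["P"] * n_pseudo + ["ORF"] * n_orf + ["F"] * (n_genes - n_pseudo - n_orf)
    rng.shuffle(defect_plan)

    v_specs = []  # (subgroup, seq, functionality, defect, flank, leader)
    gi = 0
    for sub_idx, anc in enumerate(ancestors, start=1):
        for _ in range(cfg.genes_per_subgroup):
            seq = _mutate_keeping_architecture(anc, rng, per_member)
            plan = defect_plan[gi]
            gi += 1
            flank = _good_flank(rng)
            leader = "ATG" + "".join(rng.choice(_NTS, 45))
            defect = ""
            if plan == "P":
                if rng.random() < 0.5:
                    # in-frame stop at a random interior codon
                    c = int(rng.integers(5, n_aa - 5))
                    seq = seq[: 3 * c] + "TAA" + seq[3 * c + 3 :]
                    defect = "STOP_CODON"
                else:
                    p = int(rng.integers(30, len(seq) - 30))
                    seq = seq[:p] + seq[p + 1 :]  # single-base deletion
                    defect = "FRAMESHIFT"
            elif plan == "ORF":
                flank = flank.replace(RSS_HEPTAMER, "CTCAGTG", 1)
                defect = "RSS_DEFECT"
            v_specs.append((sub_idx, seq, plan, defect, flank, leader))

    # --- D, J, C germline elements
    def _j_region() -> str:
        # J-REGION: 4 junction-tail codons, then the W-G-x-G motif, then FR4
        tail = [_random_codon(rng, "ACDEFGHIKLMNPQRSTVY") for _ in range(4)]
        motif = ["TGG", "GGC", _random_codon(rng, "ACDEGHIKLMNPQRSTVY"), "GGC"]
        fr4 = [_random_codon(rng, "ACDEGHIKLMNPQRSTVY") for _ in range(6)]
        return "".join(tail + motif + fr4)

    d_seqs = ["".join(rng.choice(_NTS, cfg.d_region_length)) for _ in range(cfg.n_d_genes)]
    j_seqs = [_j_region() for _ in range(cfg.n_j_genes)]
    tau_d_seqs = ["".join(rng.choice(_NTS, cfg.d_region_length)) for _ in range(2)]
    tau_j_seqs = [_j_region() for _ in range(2)]

    def build_locus(locus_id: str, divergence: float) -> Tuple[LocusModel, List[dict]]:
        dup = locus_id == "B"
        orientation = "FWD"
        chrom = "sim_chr2" if dup else "sim_chr1"
        pos_cursor = 10_000
        genes: List[GermlineGene] = []
        truth_rows: List[dict] = []

        def place(length: int) -> Tuple[int, int]:
            nonlocal pos_cursor
            start = pos_cursor
            pos_cursor += length + int(rng.integers(200, 400))
            return start, start + length - 1

        def diverge(seq: str) -> str:
            if divergence <= 0:
                return seq
            n = int(round(divergence * len(seq)))
            return _mutate_keeping_architecture(seq, rng, n)

        # V genes 5'->3'; positional numbering later counts 3'->5'
        n_v = len(v_specs)
        for order_idx, (sub, seq, plan, defect, flank, leader) in enumerate(v_specs):
            seq_l = diverge(seq) if dup else seq
            start, stop = place(len(seq_l))
            position = n_v - order_idx  # nearest the clusters = position 1
            gn = GeneName(group="V", subgroup=sub, duplicated=dup, position=position)
            func = {
                "F": Functionality("F"),
                "ORF": Functionality("ORF", reasons=("RSS_DEFECT",)),
                "P": Functionality(
                    "P",
                    in_frame=(defect == "STOP_CODON"),
                    reasons=(defect,) if defect else ("STOP_CODON",),
                ),
            }[plan]
            allele = GermlineAllele(
                ref=AlleleRef(gn, 1),
                functionality=func,
                v_region_nt=seq_l,
                leader_nt=leader,
                flank_3p=flank,
            )
            genes.append(
                GermlineGene(
                    name=gn, locus_id=locus_id, chromosome=chrom,
                    start=start, stop=stop, alleles=[allele],
                )
            )
            truth_rows.append(
                {
                    "name": format_gene_name(gn),
                    "locus_id": locus_id,
                    "subgroup": sub,
                    "functionality": plan,
                    "defect": defect,
                    "position": position,
                }
            )

        # one tau D-J-C cluster then the mu/delta cluster
        cluster_plan = [
            ("D", 2, "T"), ("J", 2, "T"), ("C", 1, "T"),
            ("D", cfg.n_d_genes, "M"), ("J", cfg.n_j_genes, "M"),
            ("C", 1, "M"), ("C", 1, "Delta"),
        ]
        d_i = j_i = 0
        tau_i = 0
        for group, count, tag in cluster_plan:
            for k in range(count):
                if group == "D":
                    if tag == "M":
                        seq = d_seqs[d_i % len(d_seqs)]
                        d_i += 1
                    else:
                        seq = tau_d_seqs[k % len(tau_d_seqs)]
                    gn = GeneName(
                        group="D", cluster_index=k + 1,
                        c_tag=1 if tag == "T" else None, duplicated=dup,
                    )
                elif group == "J":
                    if tag == "M":
                        seq = j_seqs[j_i % len(j_seqs)]
                        j_i += 1
                    else:
                        seq = tau_j_seqs[k % len(tau_j_seqs)]
                    gn = GeneName(
                        group="J", cluster_index=k + 1,
                        c_tag=1 if tag == "T" else None, duplicated=dup,
                    )
                else:
                    seq = "".join(rng.choice(_NTS, 120))
                    if tag == "T":
                        tau_i += 1
                        gn = GeneName(group="C", isotype="T", subgroup=tau_i, duplicated=dup)
                    else:
                        gn = GeneName(
                            group="C", isotype="M" if tag == "M" else "Delta", duplicated=dup
                        )
                seq_l = diverge(seq) if dup and group != "C" else seq
                start, stop = place(len(seq_l))
                allele = GermlineAllele(
                    ref=AlleleRef(gn, 1), functionality=Functionality("F"), v_region_nt=seq_l
                )
                genes.append(
                    GermlineGene(
                        name=gn, locus_id=locus_id, chromosome=chrom,
                        start=start, stop=stop, alleles=[allele],
                    )
                )
        locus = LocusModel(
            species="SimSp", locus_id=locus_id, chromosome=chrom,
            orientation=orientation, span=(1, pos_cursor + 1_000), genes=genes,
        )
        return locus, truth_rows

    loci = []
    truth_rows: List[dict] = []
    locus_a, rows_a = build_locus("A", 0.0)
    loci.append(locus_a)
    truth_rows.extend(rows_a)
    if cfg.duplicate_locus:
        locus_b, rows_b = build_locus("B", cfg.duplicate_divergence)
        loci.append(locus_b)
        truth_rows.extend(rows_b)

    table_rows = []
    for locus in loci:
        for g in locus.genes:
            for a in g.alleles:
                table_rows.append(
                    {
                        "name": format_gene_name(g.name),
                        "species": "SimSp",
                        "locus_id": g.locus_id,
                        "chromosome": g.chromosome,
                        "start": g.start,
                        "stop": g.stop,
                        "polarity": g.polarity,
                        "subgroup": g.name.subgroup if g.name.group == "V" else "",
                        "allele": a.ref.allele_number,
                        "functionality": a.functionality.value,
                        "in_frame": a.functionality.in_frame,
                        "sequence": a.v_region_nt,
                    }
                )
    table = GeneTable(pd.DataFrame(table_rows))
    from .igmodel import validate_gene_table

    validate_gene_table(table)
    truth = SimTruth(genes=pd.DataFrame(truth_rows))
    return loci, table, truth


def directory_from_loci(loci, group: str = "V", set_type: str = "F_ORF_INFRAME_P") -> ReferenceDirectory:
    """Collect a reference directory straight from simulated loci."""
    spec = DirectorySetSpec(set_type=set_type, species="SimSp", group=group)
    entries = []
    for locus in loci:
        for g in locus.genes:
            if g.name.group != group:
                continue
            for a in g.alleles:
                f = a.functionality
                if group == "V" and not spec.admits(f.value, f.in_frame):
                    continue
                entries.append(
                    DirectoryEntry(
                        ref=a.ref,
                        functionality=f.value,
                        locus_id=g.locus_id,
                        sequence=a.v_region_nt,
                        region_label=f"{group}-REGION",
                        species="SimSp",
                    )
                )
    return ReferenceDirectory(spec=spec, entries=entries)


def simulate_repertoire(
    directories: Dict[str, ReferenceDirectory],
    cfg: SimConfig,
    v_weights: Optional[Dict[str, float]] = None,
):
    """Draw V-D-J rearranged reads from reference directories.

    Per read: sample a V, D and J allele (``v_weights`` keyed by V allele
    reference, uniform by default), trim exonuclease-style from the joined
    ends (V 3', both D ends, J 5'), insert N additions of geometric-mean
    length on each side of D, apply uniform per-base substitutions at
    ``cfg.mutation_rate``, and optionally attach a UMI replicated
    ``cfg.umi_duplication`` times.  Returns ``(reads, truth_df)`` where
    ``reads`` is a list of (read_id, sequence, umi-or-None) and ``truth_df``
    records every draw.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    for key in ("V", "D", "J"):
        if key not in directories or not directories[key].entries:
            raise ValueError(f"missing or empty {key} directory")
    v_entries = [e for e in directories["V"].entries if e.sequence]
    d_entries = [e for e in directories["D"].entries if e.sequence]
    j_entries = [e for e in directories["J"].entries if e.sequence]

    if v_weights:
        w = np.array([v_weights.get(str(e.ref), 0.0) for e in v_entries], dtype=float)
        if w.sum() <= 0:
            raise ValueError("v_weights select no directory allele")
        w = w / w.sum()
    else:
        w = np.full(len(v_entries), 1.0 / len(v_entries))

    reads = []
    truth_rows = []
    for i in range(cfg.n_reads):
        v = v_entries[rng.choice(len(v_entries), p=w)]
        d = d_entries[rng.integers(len(d_entries))]
        j = j_entries[rng.integers(len(j_entries))]
        v_trim = int(rng.integers(0, cfg.v_trim_max + 1))
        d_trim5 = int(rng.integers(0, cfg.d_trim_max + 1))
        d_trim3 = int(rng.integers(0, cfg.d_trim_max + 1))
        j_trim = int(rng.integers(0, cfg.j_trim_max + 1))
        n1 = int(rng.geometric(1.0 / (1.0 + cfg.n_insert_mean)) - 1)
        n2 = int(rng.geometric(1.0 / (1.0 + cfg.n_insert_mean)) - 1)
        d_core = d.sequence[d_trim5 : len(d.sequence) - d_trim3]
        ins1 = "".join(rng.choice(_NTS, n1))
        ins2 = "".join(rng.choice(_NTS, n2))
        seq = (
            v.sequence[: len(v.sequence) - v_trim]
            + ins1
            + d_core
            + ins2
            + j.sequence[j_trim:]
        )
        mutated_positions = []
        if cfg.mutation_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
            mask = rng.random(len(arr)) < cfg.mutation_rate
            for p in np.nonzero(mask)[0]:
                choices = [c for c in "ACGT" if c != arr[p]]
                arr[p] = choices[rng.integers(3)]
                mutated_positions.append(int(p))
            seq = "".join(arr)
        umi = (
            "".join(rng.choice(_NTS, cfg.umi_length)) if cfg.umi_length else None
        )
        copies = cfg.umi_duplication if cfg.umi_length else 1
        for c in range(copies):
            rid = f"read{i:05d}" + (f".{c}" if copies > 1 else "")
            reads.append((rid, seq, umi))
            truth_rows.append(
                {
                    "sequence_id": rid,
                    "v_call": str(v.ref),
                    "d_call": str(d.ref),
                    "j_call": str(j.ref),
                    "v_trim": v_trim,
                    "d_trim5": d_trim5,
                    "d_trim3": d_trim3,
                    "j_trim": j_trim,
                    "n1": n1,
                    "n2": n2,
                    "ins1": ins1,
                    "ins2": ins2,
                    "d_retained": len(d_core),
                    "n_mutations": len(mutated_positions),
                    "mutated_positions": ";".join(map(str, mutated_positions)),
                    "umi": umi or "",
                }
            )
    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads, handle) -> None:
    """Write simulated reads as FASTQ (uniform high quality, UMI in header)."""
    for rid, seq, umi in reads:
        tag = f" umi={umi}" if umi else ""
        handle.write(f"@{rid}{tag}\n{seq}\n+\n{'I' * len(seq)}\n")
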