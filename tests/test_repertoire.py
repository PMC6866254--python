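"""VDJ annotation round trips, junction analysis, productivity, UMI, usage."""

from dataclasses import replace

import numpy as np
import pytest

from salmonigh.igmodel import format_gene_name, parse_allele_ref
from salmonigh.repertoire import (
    RearrangementRecord,
    aggregate_clonotypes,
    analyze_junction,
    annotate_repertoire,
    assign_v,
    call_productivity,
    dedup_umi,
    locus_share,
    usage_table,
    write_airr_tsv,
    _j_motif_codon,
    _longest_common_substring,
)
from salmonigh.simdata import (
    SimConfig,
    directory_from_loci,
    simulate_germline_locus,
    simulate_repertoire,
)


def _d_recoverable(t, vmap, dmap, jmap, min_d=5):
    """True when the planted D is identifiable from the read's true junction
    interior alone (computed from truth draws, not from the annotation)."""
    if t.v_trim > 3:
        return False
    v, j, d = vmap[t.v_call], jmap[t.j_call], dmap[t.d_call]
    core = d[t.d_trim5 : len(d) - t.d_trim3]
    motif = _j_motif_codon(j)
    junction = (
        v[len(v) - 3 : len(v) - t.v_trim] + t.ins1 + core + t.ins2 + j[t.j_trim : motif + 3]
    )
    interior = junction[3:-3]
    scores = {name: _longest_common_substring(interior, s) for name, s in dmap.items()}
    own = scores.pop(t.d_call)
    return own >= min_d and all(s < own for s in scores.values())


class TestRoundTrip:
    def test_mutation_free_reads_recover_all_calls(self, sim_directories, sim_repertoire):
        reads, truth = sim_repertoire
        records, summary = annotate_repertoire([(r[0], r[1]) for r in reads], sim_directories)
        assert summary["failed"] == 0 and summary["unassigned"] == 0
        tm = truth.set_index("sequence_id")
        vmap = {str(e.ref): e.sequence for e in sim_directories["V"].entries}
        dmap = {str(e.ref): e.sequence for e in sim_directories["D"].entries}
        jmap = {str(e.ref): e.sequence for e in sim_directories["J"].entries}
        d_checked = 0
        for rec in records:
            t = tm.loc[rec.sequence_id]
            assert [str(r) for r in rec.v_call] == [t.v_call]
            assert str(rec.j_call) == t.j_call
            if _d_recoverable(t, vmap, dmap, jmap):
                d_checked += 1
                assert rec.d_call is not None and str(rec.d_call) == t.d_call
        assert d_checked > len(records) // 2  # the conditioning keeps most reads

    def test_identical_duplicates_yield_exact_tied_pair(self):
        cfg = SimConfig(seed=9, n_reads=40, duplicate_locus=True, duplicate_divergence=0.0)
        loci, _, _ = simulate_germline_locus(cfg)
        dirs = {g: directory_from_loci(loci, group=g) for g in ("V", "D", "J")}
        reads, truth = simulate_repertoire(dirs, cfg)
        records, summary = annotate_repertoire([(r[0], r[1]) for r in reads], dirs)
        assert summary["ambiguous"] == len(records)
        tm = truth.set_index("sequence_id")
        for rec in records:
            drawn = parse_allele_ref(tm.loc[rec.sequence_id].v_call)
            twin = replace(drawn.gene, duplicated=not drawn.gene.duplicated)
            expected = sorted(
                [str(drawn), f"{format_gene_name(twin)}*{drawn.allele_number:02d}"]
            )
            assert sorted(str(r) for r in rec.v_call) == expected
            assert rec.locus_id == "ambiguous"

    def test_gene_level_recovery_above_95_percent_at_2pc_mutation(self):
        cfg = SimConfig(seed=5, n_reads=300, mutation_rate=0.02)
        loci, _, _ = simulate_germline_locus(cfg)
        dirs = {g: directory_from_loci(loci, group=g) for g in ("V", "D", "J")}
        reads, truth = simulate_repertoire(dirs, cfg)
        records, _ = annotate_repertoire([(r[0], r[1]) for r in reads], dirs)
        tm = truth.set_index("sequence_id")
        ok = sum(
            any(str(ref.gene) == tm.loc[r.sequence_id].v_call.split("*")[0] for ref in r.v_call)
            for r in records
        )
        assert ok / len(records) >= 0.95


class TestAssignV:
    def test_random_sequence_flagged_unassigned(self, sim_directories):
        rng = np.random.default_rng(13)
        probe = "".join(rng.choice(list("ACGT"), 350))
        hits, _, unassigned = assign_v(probe, sim_directories["V"])
        assert unassigned

    def test_reverse_complement_read_is_oriented(self, sim_directories, sim_repertoire):
        reads, truth = sim_repertoire
        rid, seq, _ = reads[0]
        comp = str.maketrans("ACGT", "TGCA")
        hits, oriented, _ = assign_v(seq.translate(comp)[::-1], sim_directories["V"])
        assert hits[0].strand == "-"
        assert oriented == seq
        assert str(hits[0].ref) == truth.set_index("sequence_id").loc[rid].v_call

    def test_empty_directory_raises(self, sim_directories):
        from salmonigh.refdir import DirectorySetSpec, ReferenceDirectory

        with pytest.raises(ValueError):
            assign_v("ACGT" * 30, ReferenceDirectory(DirectorySetSpec()))


class TestJunction:
    def _single_d_directories(self, sim_directories, d_seq):
        from salmonigh.igmodel import AlleleRef, parse_gene_name
        from salmonigh.refdir import DirectoryEntry, DirectorySetSpec, ReferenceDirectory

        entry = DirectoryEntry(
            AlleleRef(parse_gene_name("IGHD1"), 1), "F", "A", d_seq, "D-REGION", "S"
        )
        dirs = dict(sim_directories)
        dirs["D"] = ReferenceDirectory(DirectorySetSpec(group="D"), [entry])
        return dirs

    def test_fully_trimmed_d_is_omitted(self, sim_directories):
        v = sim_directories["V"].entries[0].sequence
        j = sim_directories["J"].entries[0].sequence
        d_seq = "CCCCCCCCCCCCCCCC"
        dirs = self._single_d_directories(sim_directories, d_seq)
        read = v + d_seq[:3] + j  # only 3 nt of D retained, below the 5-nt floor
        interior = d_seq[:3] + j[: _j_motif_codon(j)]
        assert _longest_common_substring(interior, d_seq) < 5  # no spurious context
        hits, oriented, _ = assign_v(read, dirs["V"])
        _, d_call, junction, cdr3 = analyze_junction(oriented, hits[0], dirs)
        assert d_call is None
        assert junction[:3] == v[-3:]
        assert cdr3 == junction[3:-3]

    def test_retained_d_of_6nt_is_called(self, sim_directories):
        v = sim_directories["V"].entries[0].sequence
        j = sim_directories["J"].entries[0].sequence
        d_entry = sim_directories["D"].entries[0]
        read = v + "GG" + d_entry.sequence[2:8] + "TT" + j
        hits, oriented, _ = assign_v(read, sim_directories["V"])
        _, d_call, _, _ = analyze_junction(oriented, hits[0], sim_directories)
        assert d_call is not None and str(d_call) == str(d_entry.ref)

    def test_missing_j_reports_incomplete(self, sim_directories):
        v = sim_directories["V"].entries[0].sequence
        rng = np.random.default_rng(14)
        read = v + "".join(rng.choice(list("ACGT"), 60))
        records, summary = annotate_repertoire([("r1", read)], sim_directories)
        assert summary["incomplete"] == 1
        assert records[0].status == "incomplete"


class TestProductivity:
    def _rec(self, junction):
        return RearrangementRecord(sequence_id="x", junction_nt=junction)

    def test_in_frame_stop_free_is_productive(self):
        ok, reasons = call_productivity(self._rec("TGT" + "GCA" * 4 + "TGG"))
        assert ok and reasons == ()

    def test_out_of_frame_junction(self):
        ok, reasons = call_productivity(self._rec("TGT" + "GCAGG" + "TGG"))  # 11 nt
        assert not ok and "OUT_OF_FRAME" in reasons

    def test_stop_in_junction(self):
        ok, reasons = call_productivity(self._rec("TGT" + "TAG" + "TGG"))
        assert not ok and "STOP_IN_JUNCTION" in reasons


class TestDedupUMI:
    def test_three_identical_reads_one_consensus(self):
        out = dedup_umi([("a", "ACGT", "UU"), ("b", "ACGT", "UU"), ("c", "ACGT", "UU")])
        assert out == [("UU", "ACGT", 3)]

    def test_majority_vote_on_mismatch(self):
        out = dedup_umi([("a", "ACGT", "UU"), ("b", "ACGT", "UU"), ("c", "AGGT", "UU")])
        assert out == [("UU", "ACGT", 3)]

    def test_distinct_umis_identity_transform(self):
        reads = [("a", "ACGT", "U1"), ("b", "TTTT", "U2")]
        out = dedup_umi(reads)
        assert sorted(out) == [("U1", "ACGT", 1), ("U2", "TTTT", 1)]

    def test_ragged_umis_raise(self):
        with pytest.raises(ValueError):
            dedup_umi([("a", "ACGT", "U"), ("b", "ACGT", "UU")])


class TestUsageAndClonotypes:
    def test_fractional_counting_of_ties(self, sim_directories):
        v1, v2 = sim_directories["V"].entries[0].ref, sim_directories["V"].entries[1].ref
        recs = [
            RearrangementRecord(
                sequence_id=f"r{i}", v_call=[v1, v2], productive=True,
                junction_nt="TGTGCATGG", j_call=v1,
            )
            for i in range(4)
        ]
        u = usage_table(recs)
        assert set(u["percent"].round(6)) == {50.0}

    def test_skewed_usage_recovered(self, sim_directories):
        cfg = SimConfig(seed=21, n_reads=300)
        v_entries = sim_directories["V"].entries
        g1, g2 = str(v_entries[0].ref), str(v_entries[1].ref)
        reads, truth = simulate_repertoire(
            sim_directories, cfg, v_weights={g1: 0.7, g2: 0.3}
        )
        records, _ = annotate_repertoire([(r[0], r[1]) for r in reads], sim_directories)
        productive = [r for r in records if r.productive]
        u = usage_table(records).set_index("gene")
        p1 = u.loc[str(v_entries[0].ref.gene), "percent"]
        sigma = 100 * np.sqrt(0.7 * 0.3 / len(productive))
        assert abs(p1 - 70.0) <= 3 * sigma

    def test_percentages_sum_to_100_and_counts_conserve(self, sim_directories, sim_repertoire):
        reads, _ = sim_repertoire
        records, _ = annotate_repertoire([(r[0], r[1]) for r in reads], sim_directories)
        u = usage_table(records)
        assert u["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        clono = aggregate_clonotypes(records)
        assert clono["count"].sum() == sum(r.productive for r in records)

    def test_all_records_one_clonotype(self, sim_directories):
        v = sim_directories["V"].entries[0].ref
        j = sim_directories["J"].entries[0].ref
        recs = [
            RearrangementRecord(
                sequence_id=f"r{i}", v_call=[v], j_call=j,
                junction_nt="TGTGCATGG", cdr3_nt="GCA", productive=True,
            )
            for i in range(5)
        ]
        c = aggregate_clonotypes(recs)
        assert len(c) == 1 and c.iloc[0]["count"] == 5

    def test_no_productive_records_raises(self):
        with pytest.raises(ValueError):
            usage_table([RearrangementRecord(sequence_id="r")])


def test_airr_tsv_columns(sim_directories, sim_repertoire, tmp_path):
    reads, _ = sim_repertoire
    records, _ = annotate_repertoire([(r[0], r[1]) for r in reads[:5]], sim_directories)
    out = tmp_path / "rearr.tsv"
    df = write_airr_tsv(records, out)
    header = out.read_text().splitlines()[0].split("\t")
    assert header == [
        "sequence_id", "v_call", "d_call", "j_call", "junction", "junction_aa",
        "cdr3", "productive", "locus", "v_identity", "duplicate_count",
    ]
    assert len(df) == 5


def test_empty_read_set_gives_header_only(sim_directories, tmp_path):
    records, summary = annotate_repertoire([], sim_directories)
    assert records == [] and sum(summary.values()) == 0
    out = tmp_path / "empty.tsv"
    df = write_airr_tsv(records, out)
    assert len(df) == 0 and out.read_text().startswith("sequence_id\t")
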