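"""Identity, clustering, functionality, RSS and IMGT gapping."""

import numpy as np
import pytest

from salmonigh.igmodel import (
    AlleleRef,
    Functionality,
    GermlineAllele,
    GermlineGene,
    parse_gene_name,
)
from salmonigh.subgroup_classifier import (
    IdentityMatrix,
    cluster_subgroups,
    classify_functionality,
    find_rss,
    gap_v_region,
    identity_matrix,
    pairwise_identity,
    translate,
)

COMP = str.maketrans("ACGT", "TGCA")


def _random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate_exactly(seq, rng, k):
    pos = rng.choice(len(seq), k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = _random_nt(rng, 300)
        assert pairwise_identity(s, s) == 1.0

    def test_constructed_75_percent(self):
        """Mutating exactly 75 of 300 positions gives identity 0.75 (column
        count oracle: 225 identical / 300 aligned)."""
        rng = np.random.default_rng(1)
        s = _random_nt(rng, 300)
        assert pairwise_identity(s, _mutate_exactly(s, rng, 75)) == pytest.approx(0.75)

    def test_disjoint_homopolymers(self):
        assert pairwise_identity("A" * 60, "C" * 60) == 0.0

    def test_symmetry_and_revcomp_invariance(self):
        rng = np.random.default_rng(2)
        a = _random_nt(rng, 200)
        b = _mutate_exactly(a, rng, 40)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)
        ra, rb = a.translate(COMP)[::-1], b.translate(COMP)[::-1]
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(ra, rb))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT" * 10)
        with pytest.raises(ValueError):
            pairwise_identity("ACGU" * 10, "ACGT" * 10)
        with pytest.raises(ValueError):
            pairwise_identity("ACGT", "ACGT")  # below the 30-nt floor


def _brute_force_components(labels, values, threshold):
    """Independent oracle: BFS over the >= threshold graph."""
    n = len(labels)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, stack = set(), [s]
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            stack.extend(j for j in range(n) if j != i and values[i, j] >= threshold)
        seen |= comp
        comps.append(frozenset(labels[i] for i in comp))
    return set(comps)


def _random_identity_matrix(rng, n):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return IdentityMatrix([f"S{i:02d}" for i in range(n)], v)


class TestClusterSubgroups:
    def test_spec_examples(self):
        m = IdentityMatrix(
            ["A", "B", "C"],
            np.array([[1, 0.8, 0.6], [0.8, 1, 0.6], [0.6, 0.6, 1]]),
        )
        assert cluster_subgroups(m).labels == {"A": 1, "B": 1, "C": 2}
        chain = IdentityMatrix(
            ["A", "B", "C"],
            np.array([[1, 0.8, 0.7], [0.8, 1, 0.8], [0.7, 0.8, 1]]),
        )
        # single linkage: A-B and B-C edges pull all three together
        assert set(cluster_subgroups(chain).labels.values()) == {1}
        allsame = IdentityMatrix(["A", "B"], np.ones((2, 2)))
        assert cluster_subgroups(allsame).n_subgroups == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            m = _random_identity_matrix(rng, int(rng.integers(2, 13)))
            got = cluster_subgroups(m, 0.5)
            groups = {}
            for lbl, sub in got.labels.items():
                groups.setdefault(sub, set()).add(lbl)
            assert {frozenset(g) for g in groups.values()} == _brute_force_components(
                m.labels, m.values, 0.5
            )

    def test_labels_by_smallest_member_order(self):
        m = IdentityMatrix(
            ["Z", "A", "M"],
            np.array([[1, 0.1, 0.1], [0.1, 1, 0.1], [0.1, 0.1, 1]]),
        )
        assert cluster_subgroups(m).labels == {"A": 1, "M": 2, "Z": 3}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            m = _random_identity_matrix(rng, 8)
            counts = [
                cluster_subgroups(m, t).n_subgroups for t in (0.3, 0.5, 0.7, 0.9)
            ]
            assert counts == sorted(counts)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            IdentityMatrix(["A", "B"], np.array([[1, 0.5], [0.6, 1]]))


class TestFindRSS:
    FLANK = "GGTTGG" + "CACAGTG" + "A" * 23 + "ACAAAAACC" + "TTGGTT"

    def test_exact_hit(self):
        hit = find_rss(self.FLANK, 23)
        assert (hit.score, hit.spacer_length, hit.offset) == (0, 23, 6)

    def test_single_mismatch_scored_by_hamming(self):
        hit = find_rss(self.FLANK.replace("ACAAAAACC", "ACAAAAACG"), 23)
        assert hit.score == 1

    def test_no_cac_seed_gives_none(self):
        assert find_rss("G" * 60, 23) is None

    def test_broken_heptamer_seed_gives_none(self):
        assert find_rss(self.FLANK.replace("CACAGTG", "CTCAGTG"), 23) is None

    def test_short_flank_raises(self):
        with pytest.raises(ValueError):
            find_rss("CACAGTG", 23)


def _architected_v(rng, cdr1=10, cdr2=8):
    from salmonigh.simdata import SimConfig, _v_region_ancestor

    cfg = SimConfig(seed=0, cdr1_aa=cdr1, cdr2_aa=cdr2,
                    v_region_length=3 * (82 + cdr1 + cdr2))
    return _v_region_ancestor(rng, cfg)


class TestGapVRegion:
    def test_full_length_loops_have_no_gaps(self):
        rng = np.random.default_rng(5)
        aa = translate(_architected_v(rng, cdr1=12, cdr2=10))
        g = gap_v_region(aa)
        assert "." not in g.gapped_aa
        assert (g.cdr1_length, g.cdr2_length) == (12, 10)

    def test_short_cdr1_gap_arithmetic(self):
        rng = np.random.default_rng(6)
        aa = translate(_architected_v(rng, cdr1=8, cdr2=10))
        g = gap_v_region(aa)
        cdr1_window = g.gapped_aa[26:38]
        assert cdr1_window.count(".") == 12 - 8
        # gaps at the loop top: flanks contiguous
        assert cdr1_window[:4].isalpha() and cdr1_window[-4:].isalpha()
        assert cdr1_window[4:8] == "...."

    def test_anchors_on_positions(self):
        rng = np.random.default_rng(7)
        g = gap_v_region(translate(_architected_v(rng)))
        assert g.residue(23) == "C"
        assert g.residue(41) == "W"
        assert g.residue(104) == "C"

    def test_missing_cysteines_raise(self):
        with pytest.raises(ValueError, match="CYS"):
            gap_v_region("A" * 100)


def _v_gene(seq, leader="ATG" + "G" * 45, flank=TestFindRSS.FLANK):
    gn = parse_gene_name("IGHV1-1")
    allele = GermlineAllele(
        ref=AlleleRef(gn, 1), v_region_nt=seq, leader_nt=leader, flank_3p=flank
    )
    gene = GermlineGene(
        name=gn, locus_id="A", chromosome="c", start=1, stop=len(seq), alleles=[allele]
    )
    return gene, allele


class TestClassifyFunctionality:
    def setup_method(self):
        rng = np.random.default_rng(8)
        self.seq = _architected_v(rng)

    def test_open_frame_canonical_elements_is_functional(self):
        gene, allele = _v_gene(self.seq)
        assert classify_functionality(gene, allele) == Functionality("F")

    def test_stop_codon_gives_in_frame_pseudogene(self):
        seq = self.seq[:87] + "TAA" + self.seq[90:]  # codon 30
        gene, allele = _v_gene(seq)
        f = classify_functionality(gene, allele)
        assert f.value == "P" and f.in_frame and "STOP_CODON" in f.reasons

    def test_rss_defect_gives_orf(self):
        gene, allele = _v_gene(self.seq, flank=TestFindRSS.FLANK.replace("CACAGTG", "CTCAGTG"))
        f = classify_functionality(gene, allele)
        assert f.value == "ORF" and "RSS_DEFECT" in f.reasons

    def test_strict_flank_mode_downgrades_flank_defect_to_p(self):
        gene, allele = _v_gene(self.seq, flank=TestFindRSS.FLANK.replace("CACAGTG", "CTCAGTG"))
        f = classify_functionality(gene, allele, strict_flank_mode=True)
        assert f.value == "P" and f.in_frame

    def test_frameshift_gives_out_of_frame_pseudogene(self):
        seq = self.seq[:36] + self.seq[37:]  # single-base deletion at codon 12
        gene, allele = _v_gene(seq)
        f = classify_functionality(gene, allele)
        assert f.value == "P" and not f.in_frame and "FRAMESHIFT" in f.reasons

    def test_missing_leader_init_gives_pseudogene(self):
        gene, allele = _v_gene(self.seq, leader="GTG" + "G" * 45)
        f = classify_functionality(gene, allele)
        assert f.value == "P" and "NO_INIT" in f.reasons

    def test_requires_sequence(self):
        gene, allele = _v_gene(self.seq)
        allele.v_region_nt = None
        with pytest.raises(ValueError):
            classify_functionality(gene, allele)


class TestAssignToReferenceSubgroups:
    def _directory(self):
        from salmonigh.refdir import DirectoryEntry, DirectorySetSpec, ReferenceDirectory
        from salmonigh.igmodel import AlleleRef, parse_gene_name

        rng = np.random.default_rng(9)
        self.s1 = _random_nt(rng, 300)
        self.s6 = _random_nt(rng, 300)
        entries = [
            DirectoryEntry(AlleleRef(parse_gene_name("IGHV1-1"), 1), "F", "A", self.s1),
            DirectoryEntry(AlleleRef(parse_gene_name("IGHV6-2"), 1), "F", "A", self.s6),
        ]
        return ReferenceDirectory(DirectorySetSpec(), entries)

    def test_exact_copy_matches_its_subgroup(self):
        d = self._directory()
        from salmonigh.subgroup_classifier import assign_to_reference_subgroups

        assert assign_to_reference_subgroups(self.s6, d) == 6

    def test_distant_sequence_is_new(self):
        d = self._directory()
        from salmonigh.subgroup_classifier import assign_to_reference_subgroups

        rng = np.random.default_rng(10)
        probe = _random_nt(rng, 300)
        assert assign_to_reference_subgroups(probe, d) == "NEW"

    def test_tie_breaks_to_lower_subgroup(self):
        d = self._directory()
        from salmonigh.subgroup_classifier import assign_to_reference_subgroups

        rng = np.random.default_rng(11)
        # mosaic equidistant (same mutated positions relative to each)
        probe = _mutate_exactly(self.s1, rng, 30)
        d.entries[1].sequence = _mutate_exactly(probe, np.random.default_rng(11), 30)
        i1 = pairwise_identity(probe, d.entries[0].sequence)
        i6 = pairwise_identity(probe, d.entries[1].sequence)
        if abs(i1 - i6) < 1e-12:  # constructed tie
            assert assign_to_reference_subgroups(probe, d) == 1

    def test_empty_directory_raises(self):
        from salmonigh.refdir import DirectorySetSpec, ReferenceDirectory
        from salmonigh.subgroup_classifier import assign_to_reference_subgroups

        with pytest.raises(ValueError):
            assign_to_reference_subgroups("ACGT" * 20, ReferenceDirectory(DirectorySetSpec()))
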