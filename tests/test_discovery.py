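"""Conserved matching, locus clustering, inverted repeats, folding and calling."""

import itertools

import numpy as np
import pytest
from Bio import Align

from emmir.discovery import (
    HairpinCriteria,
    InvertedRepeat,
    MatureRef,
    best_inverted_repeat_score,
    call_novel,
    cluster_loci,
    evaluate_hairpin,
    extend_repeat,
    extract_precursor,
    find_inverted_repeats,
    fold_hairpin,
    match_conserved,
    parse_family,
    PAIR_WEIGHT,
)
from emmir.genome_map import AlignmentHit
from emmir.preprocess import UniqueTag
from emmir.seqtools import revcomp

BASES = list("ACGT")


def _random_seq(rng, n):
    return "".join(rng.choice(BASES, n))


# ---------------------------------------------------------------------------
# conserved matching
# ---------------------------------------------------------------------------

class TestMatchConserved:
    REFS = [
        MatureRef("tae-miR166a", "miR166", "TCGGACCAGGCTTCATTCCCC"),
        MatureRef("tae-miR393a", "miR393", "TTCCAAAGGGATCGCATTGAT"),
    ]

    def test_exact_match_zero_mismatches(self):
        m = match_conserved("TCGGACCAGGCTTCATTCCCC", self.REFS)
        assert m is not None and m.family == "miR166" and m.n_mismatches == 0

    def test_three_substitutions_excluded(self):
        seq = "ACGGACCTGGCTTCATTCCCG"  # 3 subs from miR166a, far from miR393a
        assert match_conserved(seq, self.REFS) is None

    def test_one_nt_overhang_is_uncounted(self):
        m = match_conserved("TCGGACCAGGCTTCATTCCCCA", self.REFS)  # +1 nt at 3'
        assert m is not None and m.n_mismatches == 0

    def test_length_difference_beyond_one_ignored(self):
        assert match_conserved("TCGGACCAGGCTTCATTCCCCAA", self.REFS) is None

    def test_ties_are_recorded_and_break_by_reference_order(self):
        refs = [
            MatureRef("a-miR1", "miR1", "A" * 21),
            MatureRef("b-miR2", "miR2", "A" * 20 + "C"),
        ]
        m = match_conserved("A" * 20 + "G", refs, max_mismatches=2)
        assert m is not None and m.ref_id == "a-miR1" and m.tie

    def test_matches_equal_brute_force_hamming_scan(self):
        rng = np.random.default_rng(10)
        refs = [
            MatureRef(f"ref-miR{i}", f"miR{i}", _random_seq(rng, 21)) for i in range(20)
        ]
        for _ in range(200):
            base = refs[int(rng.integers(0, 20))].sequence
            tag = list(base)
            for pos in rng.choice(21, size=int(rng.integers(0, 5)), replace=False):
                tag[pos] = rng.choice([b for b in BASES if b != tag[pos]])
            tag = "".join(tag)
            best = min(
                (sum(a != b for a, b in zip(tag, r.sequence)), i)
                for i, r in enumerate(refs)
            )
            expected = refs[best[1]].family if best[0] <= 2 else None
            got = match_conserved(tag, refs)
            assert (got.family if got else None) == expected

    def test_family_parsing(self):
        assert parse_family("tae-miR166a-5p") == "miR166"
        assert parse_family("osa-MIR393b") == "miR393"


# ---------------------------------------------------------------------------
# locus clustering
# ---------------------------------------------------------------------------

def _hit(start, chrom="chr1", strand="+", tag="t"):
    return AlignmentHit(tag, chrom, start, start + 21, strand)


class TestClusterLoci:
    def test_gap_below_threshold_joins(self):
        loci = cluster_loci([_hit(100), _hit(250)])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 271)

    def test_exact_threshold_distance_splits(self):
        assert len(cluster_loci([_hit(100), _hit(300)])) == 2

    def test_strand_and_chromosome_separate_loci(self):
        hits = [_hit(100), _hit(150, strand="-"), _hit(100, chrom="chr2")]
        assert len(cluster_loci(hits)) == 3

    def test_matches_connected_components_on_random_hits(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        hits = [
            _hit(int(rng.integers(0, 20_000)),
                 chrom=f"chr{int(rng.integers(1, 3))}",
                 strand=rng.choice(["+", "-"]),
                 tag=f"t{i}")
            for i in range(1000)
        ]
        g = nx.Graph()
        g.add_nodes_from(range(len(hits)))
        for i, j in itertools.combinations(range(len(hits)), 2):
            a, b = hits[i], hits[j]
            if a.chrom == b.chrom and a.strand == b.strand and abs(a.start - b.start) < 200:
                g.add_edge(i, j)
        expected = nx.number_connected_components(g)
        assert len(cluster_loci(hits)) == expected


# ---------------------------------------------------------------------------
# precursor extraction
# ---------------------------------------------------------------------------

class TestExtractPrecursor:
    def test_flank_arithmetic(self):
        genome = "A" * 10_000
        locus = cluster_loci([AlignmentHit("t", "chr1", 500, 522, "+")])[0]
        prec = extract_precursor(locus, genome)
        assert (prec.start, prec.end, len(prec.sequence)) == (300, 722, 422)
        assert not prec.clipped

    def test_left_clipping_sets_flag(self):
        genome = "A" * 1000
        locus = cluster_loci([AlignmentHit("t", "chr1", 50, 72, "+")])[0]
        prec = extract_precursor(locus, genome)
        assert prec.start == 0 and prec.clipped

    def test_minus_strand_is_reverse_complement_of_plus(self):
        rng = np.random.default_rng(12)
        genome = _random_seq(rng, 2000)
        plus = extract_precursor(
            cluster_loci([AlignmentHit("t", "chr1", 800, 822, "+")])[0], genome
        )
        minus = extract_precursor(
            cluster_loci([AlignmentHit("t", "chr1", 800, 822, "-")])[0], genome
        )
        assert minus.sequence == revcomp(plus.sequence)


# ---------------------------------------------------------------------------
# inverted repeats
# ---------------------------------------------------------------------------

def oracle_best_ir_score(seq: str, min_loop: int = 3) -> int | None:
    """Independent best-score search: Smith-Waterman (Biopython) of every
    prefix against the reverse complement of every admissible suffix."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 3
    aligner.mismatch_score = -3
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -6
    best = 0
    n = len(seq)
    for b in range(1, n):
        for c in range(b + min_loop, n):
            best = max(best, aligner.score(seq[:b], revcomp(seq[c:])))
    return int(best) if best > 0 else None


class TestInvertedRepeats:
    def test_fourteen_bp_perfect_stem_scores_42(self):
        arm = "ACGTTGCAGGTCCA"
        irs = find_inverted_repeats(arm + "AATTCA" + revcomp(arm))
        assert len(irs) == 1
        ir = irs[0]
        assert ir.score == 42
        assert ir.left_arm == (0, 14) and ir.right_arm == (20, 34)

    def test_thirteen_bp_stem_misses_threshold(self):
        arm = "ACGTTGCAGGTCC"
        seq = arm + "AATTCA" + revcomp(arm)
        assert find_inverted_repeats(seq) == []
        assert best_inverted_repeat_score(seq) == 39

    def test_alignment_score_identity(self):
        rng = np.random.default_rng(13)
        arm = _random_seq(rng, 20)
        seq = _random_seq(rng, 30) + arm + "ACGATC" + revcomp(arm) + _random_seq(rng, 30)
        for ir in find_inverted_repeats(seq):
            m = sum(1 for c in ir.alignment if c[2] == "match")
            mm = sum(1 for c in ir.alignment if c[2] == "mismatch")
            g = sum(1 for c in ir.alignment if c[2] == "gap")
            assert ir.score == 3 * m - 3 * mm - 6 * g
            assert ir.left_arm[1] <= ir.right_arm[0]

    def test_scores_match_biopython_oracle_on_random_sequences(self):
        rng = np.random.default_rng(14)
        for _ in range(40):
            seq = _random_seq(rng, int(rng.integers(24, 61)))
            mine = best_inverted_repeat_score(seq)
            mine = mine if (mine is not None and mine > 0) else None
            assert mine == oracle_best_ir_score(seq)

    def test_max_repeat_span_is_enforced(self):
        arm = _random_seq(np.random.default_rng(15), 20)
        seq = arm + "T" * 300 + revcomp(arm)
        assert find_inverted_repeats(seq, max_repeat=240) == []
        assert len(find_inverted_repeats(seq, max_repeat=400)) == 1


class TestExtendRepeat:
    def _ir(self, left, right):
        return InvertedRepeat(left_arm=left, right_arm=right,
                              loop=(left[1], right[0]), score=42, alignment=[])

    def test_symmetric_padding(self):
        assert extend_repeat(self._ir((50, 64), (130, 150)), 400) == (40, 160)

    def test_clipped_at_sequence_start(self):
        assert extend_repeat(self._ir((5, 19), (80, 100)), 400) == (0, 110)


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def oracle_fold_weight(seq: str, min_loop: int = 3) -> int:
    """Interval recursion enumerating the pairing partner of position i."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    s = [code.get(b, 4) for b in seq]
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        out = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            w = PAIR_WEIGHT.get((s[i], s[k]), 0)
            if w:
                out = max(out, w + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1) if seq else 0


class TestFoldHairpin:
    def test_perfect_gc_stem(self):
        st = fold_hairpin("GGGGAAAACCCC")
        assert st.pairing == "((((....))))"
        assert st.n_pairs == 4
        assert st.mfe_proxy == -12.0

    def test_unpairable_sequence_all_dots(self):
        st = fold_hairpin("AAAAAAA")
        assert st.pairing == "." * 7 and st.n_pairs == 0

    def test_weight_matches_exhaustive_recursion(self):
        rng = np.random.default_rng(16)
        for _ in range(30):
            seq = _random_seq(rng, 20)
            st = fold_hairpin(seq)
            assert -st.mfe_proxy == oracle_fold_weight(seq)

    def test_structure_is_well_formed(self):
        rng = np.random.default_rng(17)
        seq = _random_seq(rng, 60)
        st = fold_hairpin(seq)
        depth = 0
        for ch in st.pairing:
            depth += {"(": 1, ")": -1}.get(ch, 0)
            assert depth >= 0
        assert depth == 0
        for i, p in enumerate(st.partner):
            if p >= 0:
                assert st.partner[p] == i and abs(p - i) > 3
                pair = (st.sequence[min(i, p)], st.sequence[max(i, p)])
                enc = ({"A": 0, "C": 1, "G": 2, "T": 3}[pair[0]],
                       {"A": 0, "C": 1, "G": 2, "T": 3}[pair[1]])
                assert enc in PAIR_WEIGHT

    def test_complementary_flanks_never_decrease_weight(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            seq = _random_seq(rng, 30)
            inner = -fold_hairpin(seq).mfe_proxy
            outer = -fold_hairpin("GG" + seq + "CC").mfe_proxy
            assert outer >= inner


# ---------------------------------------------------------------------------
# hairpin evaluation and novel calling
# ---------------------------------------------------------------------------

def _perfect_hairpin(rng, stem=25, loop=12):
    arm = _random_seq(rng, stem)
    return arm + _random_seq(rng, loop) + revcomp(arm)


class TestEvaluateHairpin:
    def test_planted_mature_on_perfect_stem_passes(self):
        rng = np.random.default_rng(19)
        seq = _perfect_hairpin(rng)
        st = fold_hairpin(seq)
        ev = evaluate_hairpin((2, 23), st)
        assert ev.passed, ev.reasons

    def test_mature_straddling_terminal_loop_fails(self):
        rng = np.random.default_rng(20)
        seq = _perfect_hairpin(rng)
        st = fold_hairpin(seq)
        ev = evaluate_hairpin((15, 36), st)  # spans the 25..37 loop
        assert not ev.passed
        assert "mature_spans_loop" in ev.reasons

    def test_five_unpaired_mature_positions_fail(self):
        rng = np.random.default_rng(21)
        arm = _random_seq(rng, 30)
        seq = arm + _random_seq(rng, 12) + revcomp(arm)
        st = fold_hairpin(seq)
        # refold after knocking five pairing partners out of the 3' arm
        partners = sorted(int(st.partner[i]) for i in range(2, 23))[:5]
        mutated = list(seq)
        for p in partners:
            mutated[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[p]]
        st2 = fold_hairpin("".join(mutated))
        ev = evaluate_hairpin((2, 23), st2)
        if not ev.passed:  # mutation may still leave compensatory pairing
            assert set(ev.reasons) & {"mature_unpaired_total", "mature_unpaired_run", "duplex_bulges"}

    def test_short_hairpin_fails_length_criterion(self):
        rng = np.random.default_rng(22)
        arm = _random_seq(rng, 20)
        seq = arm + "AAAA" + revcomp(arm)  # 44 nt < 60
        ev = evaluate_hairpin((0, 20), fold_hairpin(seq))
        assert "hairpin_length" in ev.reasons

    def test_mature_outside_structure_is_an_error(self):
        st = fold_hairpin("GGGGAAAACCCC")
        with pytest.raises(ValueError):
            evaluate_hairpin((5, 40), st)


class TestCallNovel:
    def _setup_locus(self, genome, mature, start):
        tag = UniqueTag(tag_id="t1", sequence=mature, counts={"S1": 30, "Ck1": 10})
        hit = AlignmentHit("t1", "chr1", start, start + len(mature), "+")
        return cluster_loci([hit]), {"t1": tag}

    def test_planted_hairpin_yields_exact_mature_call(self):
        rng = np.random.default_rng(23)
        arm = _random_seq(rng, 25)
        mature = arm[2:23]
        hairpin = arm + _random_seq(rng, 12) + revcomp(arm)
        genome = _random_seq(rng, 600) + hairpin + _random_seq(rng, 600)
        start = 600 + 2
        loci, tags = self._setup_locus(genome, mature, start)
        records = call_novel(loci, tags, genome)
        assert len(records) == 1
        assert records[0].mature_seq == mature
        assert records[0].id == "novel-1"
        assert records[0].counts == {"S1": 30, "Ck1": 10}

    def test_hairpin_free_locus_yields_no_record(self):
        # A/C alphabet admits no base pair, hence no hairpin anywhere
        rng = np.random.default_rng(24)
        genome = "".join(rng.choice(["A", "C"], 1500))
        mature = genome[700:721]
        loci, tags = self._setup_locus(genome, mature, 700)
        assert call_novel(loci, tags, genome) == []

    def test_shared_mature_across_loci_collapses_to_one_record(self):
        rng = np.random.default_rng(25)
        arm = _random_seq(rng, 25)
        mature = arm[2:23]
        hairpin = arm + _random_seq(rng, 12) + revcomp(arm)
        genome = (
            _random_seq(rng, 600) + hairpin + _random_seq(rng, 900)
            + hairpin + _random_seq(rng, 600)
        )
        tag = UniqueTag(tag_id="t1", sequence=mature, counts={"S1": 30})
        hits = [
            AlignmentHit("t1", "chr1", 602, 623, "+"),
            AlignmentHit("t1", "chr1", 600 + len(hairpin) + 900 + 2,
                         600 + len(hairpin) + 900 + 23, "+"),
        ]
        records = call_novel(cluster_loci(hits), {"t1": tag}, genome)
        assert len(records) == 1
        assert len(records[0].precursors) == 2
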