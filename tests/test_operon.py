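"""Alignment, homology calls, conservation patterns and synteny checks."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutiron.operon import (
    HMU_GENES,
    Alignment,
    GeneLocus,
    ProteinSeq,
    check_synteny,
    conservation_pattern,
    detect_homologs,
    global_align,
    percent_identity,
    survey_genome,
    tally_patterns,
)
from gutiron.synthetic import gen_genome_layout, gen_protein_family

MATCH, MISMATCH, GAP = 2.0, -1.0, -2.0


def brute_force_score(a: str, b: str) -> float:
    """Independent oracle: enumerate every global alignment path."""
    best = [float("-inf")]

    def rec(i: int, j: int, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (MATCH if a[i] == b[j] else MISMATCH))
        if i < len(a):
            rec(i + 1, j, score + GAP)
        if j < len(b):
            rec(i, j + 1, score + GAP)

    rec(0, 0, 0.0)
    return best[0]


def all_seqs(alphabet: str, max_len: int):
    for n in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=n):
            yield "".join(tup)


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align(ProteinSeq("a", "ACDE"), ProteinSeq("b", "ACDE"))
        assert aln.score == 8.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_gap(self):
        aln = global_align(ProteinSeq("a", "ACDE"), ProteinSeq("b", "ACE"))
        assert aln.score == 3 * MATCH + GAP == 4.0
        assert aln.aligned_b.count("-") == 1

    def test_matches_exhaustive_enumeration_short(self):
        # every pair over a 4-letter alphabet up to length 3
        seqs = list(all_seqs("ACGT", 3))
        for a in seqs:
            for b in seqs:
                aln = global_align(ProteinSeq("a", a), ProteinSeq("b", b))
                assert aln.score == brute_force_score(a, b), (a, b)

    def test_matches_exhaustive_enumeration_sampled_len6(self):
        # randomized sample of longer pairs (up to length 6), same oracle
        import random

        rng = random.Random(17)
        for _ in range(150):
            a = "".join(rng.choices("ACGT", k=rng.randint(4, 6)))
            b = "".join(rng.choices("ACGT", k=rng.randint(4, 6)))
            aln = global_align(ProteinSeq("a", a), ProteinSeq("b", b))
            assert aln.score == brute_force_score(a, b), (a, b)

    def test_matches_biopython_aligner_on_random_pairs(self):
        from Bio import Align
        import random

        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=MATCH,
            mismatch_score=MISMATCH,
            open_gap_score=GAP,
            extend_gap_score=GAP,
        )
        rng = random.Random(3)
        for _ in range(20):
            a = "".join(rng.choices("ACDEFGHIKL", k=rng.randint(10, 40)))
            b = "".join(rng.choices("ACDEFGHIKL", k=rng.randint(10, 40)))
            ours = global_align(ProteinSeq("a", a), ProteinSeq("b", b)).score
            assert ours == aligner.score(a, b)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a=st.text("ACDE", min_size=1, max_size=12),
        b=st.text("ACDE", min_size=1, max_size=12),
    )
    def test_score_symmetric(self, a, b):
        sa, sb = ProteinSeq("a", a), ProteinSeq("b", b)
        assert global_align(sa, sb).score == global_align(sb, sa).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align(ProteinSeq("a", "ACDE"), ProteinSeq("b", ""))


class TestPercentIdentity:
    def test_identical_is_100(self):
        aln = global_align(ProteinSeq("a", "MKVLH"), ProteinSeq("b", "MKVLH"))
        assert percent_identity(aln) == 100.0

    def test_gap_columns_count_in_denominator(self):
        aln = global_align(ProteinSeq("a", "ACDE"), ProteinSeq("b", "ACE"))
        assert percent_identity(aln) == 75.0

    def test_family_identity_near_target(self):
        fam = gen_protein_family(300, 40.0, 3, seed=6)
        for seq in fam[1:]:
            ident = percent_identity(global_align(fam[0], seq))
            assert 37.0 <= ident <= 43.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            percent_identity(Alignment("", "", 0.0))


class TestDetectHomologs:
    def test_bait_hits_itself_at_100(self):
        fam = gen_protein_family(120, 60.0, 2, seed=0)
        bait = fam[0]
        hits = detect_homologs(bait, fam)
        assert hits[0].id == "ancestor" and hits[0].identity == 100.0

    def test_below_threshold_family_not_hit(self):
        fam = gen_protein_family(200, 25.0, 2, seed=1)
        hits = detect_homologs(fam[0], fam[1:], threshold=30.0)
        assert hits == []

    def test_two_planted_copies_found(self):
        fam = gen_protein_family(120, 60.0, 2, seed=2)
        hits = detect_homologs(fam[0], fam[1:], threshold=30.0)
        assert len(hits) == 2

    def test_empty_proteome_is_empty_result(self):
        fam = gen_protein_family(50, 90.0, 1, seed=3)
        assert detect_homologs(fam[0], []) == []

    def test_identity_symmetric_between_hit_pairs(self):
        fam = gen_protein_family(150, 55.0, 2, seed=4)
        a, b = fam[0], fam[1]
        ab = percent_identity(global_align(a, b))
        ba = percent_identity(global_align(b, a))
        assert ab == ba


def _baits(length=120):
    """Six mutually unrelated bait proteins, keyed hmuY..hmuV."""
    return {
        gene: ProteinSeq(gene, gen_protein_family(length, 100.0, 1, seed=100 + i)[0].residues)
        for i, gene in enumerate(HMU_GENES)
    }


def _derived(bait: ProteinSeq, identity: float, seed: int, name: str) -> ProteinSeq:
    """One homolog of ``bait`` at a controlled identity."""
    import numpy as np

    rng = np.random.default_rng(seed)
    residues = list(bait.residues)
    n_sub = round(len(residues) * (100.0 - identity) / 100.0)
    sites = rng.choice(len(residues), size=n_sub, replace=False)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for s in sites:
        choices = [c for c in alphabet if c != residues[s]]
        residues[s] = choices[rng.integers(len(choices))]
    return ProteinSeq(name, "".join(residues))


class TestConservationPatterns:
    def test_constructed_genomes_reproduce_patterns(self):
        baits = _baits()
        full = [_derived(baits[g], 60.0, i, f"p{i}") for i, g in enumerate(HMU_GENES)]
        partial = [
            _derived(baits[g], 60.0, 10 + i, f"q{i}")
            for i, g in enumerate(HMU_GENES)
            if g in ("hmuR", "hmuT", "hmuU", "hmuV")
        ]
        dup_r = [
            _derived(baits["hmuR"], 60.0, 20, "r1"),
            _derived(baits["hmuR"], 55.0, 21, "r2"),
        ] + [
            _derived(baits[g], 60.0, 30 + i, f"s{i}")
            for i, g in enumerate(("hmuT", "hmuU", "hmuV"))
        ]
        assert survey_genome("g_full", baits, full).pattern == "111111"
        assert survey_genome("g_partial", baits, partial).pattern == "010111"
        assert survey_genome("g_dup", baits, dup_r).pattern == "020111"

    def test_wrong_bait_count_rejected(self):
        with pytest.raises(ValueError, match="6 bait"):
            conservation_pattern("g", [[], []])

    def test_scoring_rule(self):
        hit = lambda n: [object()] * n
        pat = conservation_pattern("g", [hit(0), hit(2), hit(0), hit(1), hit(1), hit(3)])
        assert pat.pattern == "020112"


class TestTallyPatterns:
    def test_exact_counts_sorted(self):
        from gutiron.operon import ConservationPattern

        pats = (
            [ConservationPattern(f"a{i}", "111111") for i in range(6)]
            + [ConservationPattern(f"b{i}", "010111") for i in range(3)]
            + [ConservationPattern("c0", "000111")]
        )
        tally = tally_patterns(pats)
        assert tally == [("111111", 6), ("010111", 3), ("000111", 1)]
        assert sum(n for _, n in tally) == len(pats)

    def test_empty_input(self):
        assert tally_patterns([]) == []


class TestCheckSynteny:
    def test_generated_full_operon_is_syntenic(self):
        loci = gen_genome_layout("111111", gap_bp=500)
        rep = check_synteny(loci, genome_id="g")
        assert rep.colocalized and rep.order_preserved
        assert rep.max_gap_bp == 500

    def test_shuffled_layout_breaks_order(self):
        loci = gen_genome_layout("111111", shuffle=True, seed=8)
        rep = check_synteny(loci)
        assert rep.colocalized and not rep.order_preserved

    def test_distant_gene_breaks_colocalization(self):
        loci = gen_genome_layout("111111", gap_bp=500)
        moved = loci[:-1] + [
            GeneLocus("hmuV", loci[-1].contig, loci[-1].start + 10**6, loci[-1].end + 10**6)
        ]
        rep = check_synteny(moved)
        assert not rep.colocalized

    def test_reverse_order_counts_as_preserved(self):
        loci = gen_genome_layout("111111", gap_bp=100)
        span = loci[-1].end + 10
        flipped = [
            GeneLocus(x.gene, x.contig, span - x.end, span - x.start, "-") for x in loci
        ]
        rep = check_synteny(flipped)
        assert rep.order_preserved

    def test_single_locus_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            check_synteny(gen_genome_layout("100000"))
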