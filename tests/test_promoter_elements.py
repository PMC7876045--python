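import itertools
import math

import numpy as np
import pytest

from sigmapause import (
    build_ri_model,
    classify_tssR,
    find_minus10R,
    info_profile,
    ri_score,
    revcomp,
    scan_minus10LR,
    spacer_ri_table,
)
from sigmapause.promoter_elements import BASES, annotate_promoter, oriented_slice

from conftest import tss


def random_seqs(rng, n, width):
    return ["".join(rng.choice(list(BASES), width)) for _ in range(n)]


def oracle_ri(model, seq):
    """Independent per-position table lookup."""
    return sum(model.weights[BASES.index(b), l] for l, b in enumerate(seq))


class TestBuildRiModel:
    def test_single_motif_degenerate(self):
        model = build_ri_model(["TATAAT"] * 4, pseudocount=0.0)
        assert model.freqs[BASES.index("T"), 0] == 1.0
        assert model.weights[BASES.index("T"), 0] == pytest.approx(2.0)
        assert model.rsequence == pytest.approx(12.0)

    def test_uniform_training_zero_bits(self):
        seqs = [b * 6 for b in BASES]
        model = build_ri_model(seqs, pseudocount=0.0)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-12)
        assert model.rsequence == pytest.approx(0.0)
        assert ri_score(model, "GATTCA") == pytest.approx(0.0)

    def test_frequencies_sum_to_one(self, rng):
        model = build_ri_model(random_seqs(rng, 50, 6))
        np.testing.assert_allclose(model.freqs.sum(axis=0), 1.0)

    def test_mean_ri_equals_rsequence_at_zero_pc(self, rng):
        seqs = random_seqs(rng, 100, 6)
        model = build_ri_model(seqs, pseudocount=0.0)
        mean_ri = np.mean([ri_score(model, s) for s in seqs])
        assert abs(mean_ri - model.rsequence) < 1e-6

    def test_pseudocount_gap_shrinks_with_n(self, rng):
        gaps = []
        for n in (20, 200, 2000):
            seqs = ["TATAAT" if rng.random() < 0.8 else random_seqs(rng, 1, 6)[0] for _ in range(n)]
            model = build_ri_model(seqs, pseudocount=0.25)
            mean_ri = np.mean([ri_score(model, s) for s in seqs])
            gaps.append(abs(mean_ri - model.rsequence))
        assert gaps[2] < gaps[0]

    def test_ambiguous_base_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            build_ri_model(["TATAAT", "TATNAT"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            build_ri_model(["TATAAT", "TATAA"])

    def test_too_few_sequences(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_ri_model(["TATAAT"])

    def test_permutation_invariance(self, rng):
        seqs = random_seqs(rng, 40, 6)
        m1 = build_ri_model(seqs)
        m2 = build_ri_model(list(rng.permutation(seqs)))
        np.testing.assert_allclose(m1.freqs, m2.freqs)


class TestRiScore:
    def test_consensus_single_motif_is_12_bits(self):
        model = build_ri_model(["TATAAT"] * 4, pseudocount=0.0)
        assert ri_score(model, "TATAAT") == pytest.approx(12.0)

    def test_length_mismatch_rejected(self, rng):
        model = build_ri_model(random_seqs(rng, 10, 6))
        with pytest.raises(ValueError, match="length"):
            ri_score(model, "TATAATT")

    def test_matches_lookup_oracle(self, rng):
        model = build_ri_model(random_seqs(rng, 60, 6))
        for seq in random_seqs(rng, 200, 6):
            assert ri_score(model, seq) == pytest.approx(oracle_ri(model, seq))

    def test_consensus_dominates_all_hexamers(self, noisy_minus10_model):
        model = noisy_minus10_model
        best = max(
            ("".join(h) for h in itertools.product(BASES, repeat=6)),
            key=lambda h: ri_score(model, h),
        )
        assert ri_score(model, best) == pytest.approx(ri_score(model, model.consensus))

    def test_mutation_toward_consensus_raises_ri(self, noisy_minus10_model):
        model = noisy_minus10_model
        consensus = model.consensus
        start = "GCGCGC"
        for l in range(6):
            if start[l] == consensus[l]:
                continue
            mutated = start[:l] + consensus[l] + start[l + 1 :]
            assert ri_score(model, mutated) > ri_score(model, start)
        # and away from consensus lowers it
        for l in range(6):
            worst = min(BASES, key=lambda b: model.weights[BASES.index(b), l])
            if consensus[l] == worst:
                continue
            mutated = consensus[:l] + worst + consensus[l + 1 :]
            assert ri_score(model, mutated) < ri_score(model, consensus)


def planted_genome(rng, flank, element, spacer, tss_at, strand="+", length=400):
    """Random genome with `element` planted upstream of a TSS at `tss_at`."""
    seq = list("".join(rng.choice(list(BASES), length)))
    if strand == "+":
        start = tss_at - spacer - len(element)
        seq[start : start + len(element)] = element
    else:
        start = tss_at + spacer + 1
        seq[start : start + len(element)] = revcomp(element)
    return {"c": "".join(seq)}


class TestFindMinus10R:
    def test_planted_consensus_recovered(self, rng, noisy_minus10_model):
        hits = 0
        for trial in range(20):
            genome = planted_genome(rng, 50, "TATAAT", 6, 200)
            result = find_minus10R(noisy_minus10_model, genome, tss(200))
            hit, spacer = result
            # exhaustive oracle over every allowed placement
            best = max(
                range(3, 10),
                key=lambda s: ri_score(
                    noisy_minus10_model, genome["c"][200 - s - 6 : 200 - s]
                ),
            )
            want = genome["c"][200 - best - 6 : 200 - best]
            assert hit.sequence == want or ri_score(
                noisy_minus10_model, hit.sequence
            ) == pytest.approx(ri_score(noisy_minus10_model, want))
            if spacer == 6 and hit.sequence == "TATAAT":
                hits += 1
        assert hits >= 18  # random flanks rarely out-score consensus

    def test_identical_hexamers_spacer6_wins(self):
        # a run of T at [38,45) realises the consensus TTTTTT at both the
        # spacer-5 and spacer-6 placements upstream of a TSS at 50
        model = build_ri_model(["TTTTTT"] * 4, pseudocount=0.25)
        seq = ["G"] * 100
        seq[38:45] = "T" * 7
        hit, spacer = find_minus10R(model, {"c": "".join(seq)}, tss(50))
        assert hit.sequence == "TTTTTT"
        assert spacer == 6

    def test_uniform_model_all_tie_spacer6_preferred(self):
        uniform = build_ri_model([b * 6 for b in BASES], pseudocount=0.0)
        hit, spacer = find_minus10R(uniform, {"c": "A" * 100}, tss(50))
        assert hit.ri == pytest.approx(0.0)
        assert spacer == 6  # every placement ties at 0 bits; 6 preferred, then 7

    def test_reverse_strand_mirror(self, rng, noisy_minus10_model):
        genome_fwd = planted_genome(rng, 50, "TATAAT", 6, 200, "+")
        genome_rev = {"c": revcomp(genome_fwd["c"])}
        L = len(genome_fwd["c"])
        fwd = find_minus10R(noisy_minus10_model, genome_fwd, tss(200, "+"))
        rev = find_minus10R(noisy_minus10_model, genome_rev, tss(L - 1 - 200, "-"))
        assert fwd[0].sequence == rev[0].sequence
        assert fwd[1] == rev[1]
        assert fwd[0].ri == pytest.approx(rev[0].ri)

    def test_insufficient_upstream_sequence(self, noisy_minus10_model, caplog):
        genome = {"c": "ACGTACGTACGT"}
        with caplog.at_level("WARNING"):
            result = find_minus10R(noisy_minus10_model, genome, tss(5))
        assert result is None


class TestClassifyTssR:
    @pytest.mark.parametrize("triplet,is_yry", [("CAT", True), ("GAT", False), ("TGC", True)])
    def test_triplets(self, triplet, is_yry):
        genome = {"c": "GGGG" + triplet + "GGGG"}
        got = classify_tssR(genome, tss(5))
        assert got == (triplet, is_yry)

    def test_minus_strand(self):
        # oriented CAT at a minus-strand TSS: genomic revcomp(CAT)=ATG at TSS+1..TSS-1
        genome = {"c": "GGG" + "ATG" + "GGG"}
        got = classify_tssR(genome, tss(4, "-"))
        assert got == ("CAT", True)

    def test_edge_returns_none(self):
        assert classify_tssR({"c": "ACGT"}, tss(0)) is None


class TestScanMinus10LR:
    def test_planted_at_each_anchor(self, rng, noisy_minus10_model):
        for anchor_offset in (-1, 0, 1, 2):
            seq = list("".join(rng.choice(list("GC"), 100)))
            start = 50 + anchor_offset - 1  # second base at the anchor
            seq[start : start + 6] = "TATAAT"
            genome = {"c": "".join(seq)}
            hit = scan_minus10LR(noisy_minus10_model, genome, tss(50))
            assert hit.sequence == "TATAAT"
            assert hit.offset == anchor_offset - 1
            # exhaustive 4-placement oracle
            best = max(
                (-1, 0, 1, 2),
                key=lambda a: ri_score(
                    noisy_minus10_model, genome["c"][50 + a - 1 : 50 + a + 5]
                ),
            )
            assert best == anchor_offset

    def test_uniform_model_leftmost_anchor(self):
        uniform = build_ri_model([b * 6 for b in BASES], pseudocount=0.0)
        genome = {"c": "A" * 60}
        hit = scan_minus10LR(uniform, genome, tss(30))
        assert hit.ri == pytest.approx(0.0)
        assert hit.offset == -2  # second base at anchor -1, the leftmost

    def test_reports_negative_ri_when_no_site(self, noisy_minus10_model):
        genome = {"c": "GC" * 50}
        hit = scan_minus10LR(noisy_minus10_model, genome, tss(50))
        assert hit is not None and hit.ri <= 0.0

    def test_start_anchor_mode(self, noisy_minus10_model):
        seq = list("GC" * 50)
        seq[51:57] = "TATAAT"  # first base at offset +1
        hit = scan_minus10LR(
            noisy_minus10_model, {"c": "".join(seq)}, tss(50), anchor="start"
        )
        assert hit.sequence == "TATAAT" and hit.offset == 1

    def test_insufficient_sequence_none(self, noisy_minus10_model, caplog):
        with caplog.at_level("WARNING"):
            assert scan_minus10LR(noisy_minus10_model, {"c": "ACGTA"}, tss(2)) is None


class TestSpacerRiTable:
    def test_single_spacer_single_column(self, rng, noisy_minus10_model):
        proms = []
        for i in range(10):
            genome = planted_genome(rng, 50, "TATAAT", 6, 200)
            proms.append(
                annotate_promoter(noisy_minus10_model, genome, tss(200, id=f"t{i}"))
            )
        counts, row_marg, col_marg = spacer_ri_table(proms)
        assert row_marg.sum() == 10
        spacer_rows = counts.sum(axis=1)
        assert spacer_rows.idxmax() == 6

    def test_empty_input(self):
        counts, row_marg, col_marg = spacer_ri_table([])
        assert counts.empty

    def test_marginals_match_direct_tally(self, rng, noisy_minus10_model):
        proms = []
        for i in range(30):
            spacer = int(rng.integers(4, 9))
            genome = planted_genome(rng, 50, "TATAAT", spacer, 200)
            proms.append(
                annotate_promoter(noisy_minus10_model, genome, tss(200, id=f"t{i}"))
            )
        counts, row_marg, col_marg = spacer_ri_table(proms)
        from collections import Counter

        tally = Counter(p.spacer for p in proms)
        for spacer, n in tally.items():
            assert row_marg[spacer] == n
        assert counts.to_numpy().sum() == 30 == col_marg.sum()


class TestInfoProfile:
    def test_invariant_column_two_bits(self):
        info, heights = info_profile(["TA", "TC", "TG"])
        assert info[0] == pytest.approx(2.0)
        assert heights[BASES.index("T"), 0] == pytest.approx(2.0)

    def test_uniform_column_zero_bits(self):
        info, _ = info_profile(["A", "C", "G", "T"])
        assert info[0] == pytest.approx(0.0)

    def test_matches_entropy_oracle(self, rng):
        seqs = random_seqs(rng, 40, 8)
        info, heights = info_profile(seqs)
        for l in range(8):
            column = [s[l] for s in seqs]
            freqs = [column.count(b) / len(column) for b in BASES]
            h = -sum(f * math.log2(f) for f in freqs if f > 0)
            assert info[l] == pytest.approx(2.0 - h)
            for j, b in enumerate(BASES):
                assert heights[j, l] == pytest.approx(freqs[j] * (2.0 - h))


def test_oriented_slice_strand_symmetry():
    genome = {"c": "AACCGGTTAACC"}
    t_plus = tss(6)
    t_minus = tss(5, "-")
    assert oriented_slice(genome, t_plus, -2, 2) == "GGTTA"  # positions 4..8
    # minus-strand TSS at 5 reads the reverse complement 3'->5'
    assert oriented_slice(genome, t_minus, -2, 2) == revcomp(genome["c"][3:8])
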