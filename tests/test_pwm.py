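"""PWM construction, relative scanning and the allelic affinity test."""
import math

import numpy as np
import pytest

from regprio.annotate import Variant
from regprio.pwm import (
    PFMRecord,
    affinity_diff_test,
    allelic_best_scores,
    best_scores_at,
    build_pwm,
    call_differential_affinity,
    encode_sequence,
    filter_by_ic,
    relative_score,
)
from regprio.simulate import default_planted_pfm

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_best(model, seq):
    """Independent exhaustive enumeration of all windows on both strands."""
    L = model.length
    span = model.max_score - model.min_score
    best = None
    for i in range(len(seq) - L + 1):
        win = seq[i : i + L].upper()
        if any(c not in "ACGT" for c in win):
            continue
        for s in (win, revcomp(win)):
            raw = 0.0
            for j, c in enumerate(s):
                raw += model.log_odds["ACGT".index(c), j]
            rel = 100.0 * (raw - model.min_score) / span
            if best is None or rel > best:
                best = rel
    return best


def random_pfm(rng, L=None):
    L = L or int(rng.integers(5, 9))
    return PFMRecord(
        matrix_id="R1", tf_name="R", counts=rng.integers(0, 30, (4, L)) + 1
    )


class TestBuildPwm:
    def test_uniform_counts_zero_ic_zero_logodds(self):
        m = build_pwm(PFMRecord("U", "U", np.full((4, 6), 10.0)))
        assert m.ic == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(m.log_odds, 0.0)

    def test_deterministic_columns_approach_two_bits_each(self):
        counts = np.zeros((4, 10))
        counts[0] = 100  # all-A columns
        m = build_pwm(PFMRecord("D", "D", counts), pseudocount=1e-9)
        assert m.ic == pytest.approx(20.0, abs=1e-3)

    def test_toy_matrix_matches_hand_arithmetic(self):
        counts = np.array(
            [[8.0, 0.0, 2.0, 4.0],
             [1.0, 9.0, 2.0, 3.0],
             [0.0, 1.0, 4.0, 2.0],
             [1.0, 0.0, 2.0, 1.0]]
        )
        m = build_pwm(PFMRecord("T", "T", counts), pseudocount=0.8)
        # independent arithmetic with plain loops
        ic = 0.0
        for j in range(4):
            colsum = sum(counts[b][j] for b in range(4))
            h = 2.0
            for b in range(4):
                p = (counts[b][j] + 0.8 * 0.25) / (colsum + 0.8)
                h += p * math.log2(p)
                expected_lo = math.log2(p / 0.25)
                assert m.log_odds[b, j] == pytest.approx(expected_lo)
            ic += h
        assert m.ic == pytest.approx(ic)

    def test_bad_background_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(PFMRecord("T", "T", np.ones((4, 5))), background=[0.5, 0.5, 0.5, 0.5])


class TestIcFilter:
    def test_strictly_greater_than_threshold(self):
        counts = np.zeros((4, 10))
        counts[0] = 100
        strong = build_pwm(PFMRecord("S", "S", counts), pseudocount=1e-9)
        weak = build_pwm(PFMRecord("W", "W", np.full((4, 6), 10.0)))
        at_threshold = build_pwm(PFMRecord("A", "A", counts), pseudocount=1e-9)
        at_threshold.ic = 10.0
        kept = filter_by_ic([strong, weak, at_threshold], ic_min=10.0)
        assert [m.matrix_id for m in kept] == ["S"]

    def test_mixed_set_matches_per_matrix_classification(self, rng):
        models = [build_pwm(random_pfm(rng)) for _ in range(10)]
        kept = filter_by_ic(models, ic_min=5.0)
        assert kept == [m for m in models if m.ic > 5.0]


class TestRelativeScore:
    def test_consensus_scores_100_at_offset_zero(self):
        m = build_pwm(default_planted_pfm())
        score, offset, strand = relative_score(m, m.consensus)
        assert score == pytest.approx(100.0)
        assert offset == 0 and strand == "+"

    def test_anti_consensus_window_scores_zero_on_its_strand(self):
        from regprio.pwm import _window_scores

        m = build_pwm(default_planted_pfm())
        worst = "".join("ACGT"[i] for i in np.argmin(m.log_odds, axis=0))
        fwd, _ = _window_scores(m, encode_sequence(worst))
        assert m.to_relative(fwd[0]) == pytest.approx(0.0, abs=1e-12)
        assert fwd[0] == pytest.approx(m.min_score)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(5):
            m = build_pwm(random_pfm(rng))
            seq = "".join(rng.choice(list("ACGT"), 200))
            got, _, _ = relative_score(m, seq)
            assert got == pytest.approx(brute_force_best(m, seq), abs=1e-9)

    def test_reverse_complement_invariance(self, rng):
        for _ in range(5):
            m = build_pwm(random_pfm(rng))
            seq = "".join(rng.choice(list("ACGT"), 120))
            assert relative_score(m, seq)[0] == pytest.approx(
                relative_score(m, revcomp(seq))[0], abs=1e-9
            )

    def test_windows_with_n_skipped(self):
        m = build_pwm(default_planted_pfm())
        seq = "N" * 5 + m.consensus + "N" * 5
        score, offset, _ = relative_score(m, seq)
        assert score == pytest.approx(100.0) and offset == 5

    def test_all_n_sequence_gives_nan(self):
        m = build_pwm(default_planted_pfm())
        score, offset, strand = relative_score(m, "N" * 30)
        assert math.isnan(score) and offset == -1 and strand is None


class TestAllelicScores:
    def genome_with_motif(self, rng, model, center=200):
        seq = list("".join(rng.choice(list("ACGT"), 400)))
        probs = model.background[:, None] * np.exp2(model.log_odds)
        col_ic = 2.0 + np.where(probs > 0, probs * np.log2(probs), 0.0).sum(axis=0)
        top = int(np.argmax(col_ic))
        start = center - top
        seq[start : start + model.length] = list(model.consensus)
        return {"chr1": "".join(seq)}, top

    def test_planted_consensus_major_100_minor_lower(self, rng):
        m = build_pwm(default_planted_pfm())
        genome, top = self.genome_with_motif(rng, m)
        worst = "ACGT"[int(np.argmin(m.log_odds[:, top]))]
        v = Variant("v", "chr1", 200, major=m.consensus[top], minor=worst, maf=0.2)
        s_maj, s_min = allelic_best_scores(m, genome, v)
        assert s_maj == pytest.approx(100.0)
        assert s_min < s_maj

    def test_reference_mismatch_names_snp(self, rng):
        m = build_pwm(default_planted_pfm())
        genome = {"chr1": "A" * 100}
        v = Variant("rsX", "chr1", 50, major="C", minor="T", maf=0.2)
        with pytest.raises(ValueError, match="rsX"):
            allelic_best_scores(m, genome, v)

    def test_identical_center_base_identical_scores(self, rng):
        m = build_pwm(default_planted_pfm())
        codes = encode_sequence("".join(rng.choice(list("ACGT"), 61)))
        assert best_scores_at(m, codes, 30) == best_scores_at(m, codes.copy(), 30)

    def test_palindromic_motif_strand_symmetry(self, rng):
        # palindrome: column j is the complement of column L-1-j
        counts = np.array(
            [[10, 1, 5, 2, 1, 1],
             [1, 10, 2, 5, 1, 1],
             [1, 1, 5, 2, 10, 1],
             [1, 1, 2, 5, 1, 10]], dtype=float
        )
        assert np.allclose(counts, counts[::-1, ::-1])
        m = build_pwm(PFMRecord("P", "P", counts))
        seq = "".join(rng.choice(list("ACGT"), 80))
        fwd_best, _, _ = relative_score(m, seq)
        rev_best, _, _ = relative_score(m, revcomp(seq))
        assert fwd_best == pytest.approx(rev_best, abs=1e-9)


class TestAffinityCall:
    def test_zero_diff_p_is_one(self, rng):
        bg = rng.normal(0, 5, 1000)
        assert affinity_diff_test(0.0, bg) == 1.0

    def test_extreme_diff_hits_add_one_floor(self, rng):
        bg = rng.normal(0, 1, 10_000)
        assert affinity_diff_test(1e6, bg) == pytest.approx(1 / 10_001)

    def test_diff_at_95th_percentile_gives_p_near_05(self, rng):
        bg = rng.normal(0, 5, 20_000)
        d = float(np.quantile(np.abs(bg), 0.95))
        assert affinity_diff_test(d, bg) == pytest.approx(0.05, abs=0.005)

    @pytest.mark.parametrize(
        "p,s_maj,s_min,expected_call,expected_dir",
        [
            (0.04, 85.0, 70.0, True, "decrease"),
            (0.04, 75.0, 70.0, False, "decrease"),
            (0.2, 95.0, 60.0, False, "decrease"),
            (0.05, 70.0, 90.0, True, "increase"),
        ],
    )
    def test_call_thresholds(self, p, s_maj, s_min, expected_call, expected_dir):
        call, direction = call_differential_affinity(s_maj, s_min, p)
        assert call is expected_call and direction == expected_dir
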