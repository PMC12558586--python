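"""PWM construction, the exact score null, scanning, and gain/loss calls."""

import itertools

import numpy as np
import pytest

from regswitch.motifs import (
    MotifModel, build_pwm, call_perturbation, exact_score_null, scan_window,
)


def random_counts(rng, width):
    return rng.integers(0, 30, size=(4, width)).astype(float) + rng.random((4, width))


def enumerate_tail(null):
    """Independent oracle: tail probabilities by brute force over all 4^w
    words, using the same discretized column scores and word probabilities
    under the uniform background."""
    int_pwm = null.int_pwm
    w = int_pwm.shape[1]
    totals = {}
    for word in itertools.product(range(4), repeat=w):
        t = int(sum(int_pwm[b, j] for j, b in enumerate(word)))
        totals[t] = totals.get(t, 0) + 1
    support = sorted(totals)
    tail = {}
    acc = 0
    for t in reversed(support):
        acc += totals[t]
        tail[t] = acc / 4 ** w
    return tail


class TestBuildPwm:
    def test_uniform_column_gives_zero_log_odds(self):
        counts = np.array([[1.0], [1.0], [1.0], [1.0]])
        m = build_pwm("m", counts, pseudocount=0.0)
        assert np.allclose(m.pwm, 0.0)

    def test_pseudocount_column_arithmetic(self):
        # column [2,0,0,2], pseudocount 1 split uniformly: p = (c + 0.25)/5
        counts = np.array([[2.0], [0.0], [0.0], [2.0]])
        m = build_pwm("m", counts, pseudocount=1.0)
        assert np.allclose(
            m.pwm[:, 0],
            np.log2(np.array([0.45, 0.05, 0.05, 0.45]) / 0.25),
        )
        assert m.pwm[0, 0] == pytest.approx(np.log2(1.8))

    def test_counts_proportional_to_background_give_zero(self):
        bg = [0.3, 0.2, 0.2, 0.3]
        counts = 10 * np.array(bg)[:, None] * np.ones((1, 3))
        m = build_pwm("m", counts, pseudocount=0.8, background=bg)
        assert np.allclose(m.pwm, 0.0)

    def test_zero_column_without_pseudocount_is_error(self):
        with pytest.raises(ValueError, match="all-zero column"):
            build_pwm("m", np.zeros((4, 2)), pseudocount=0.0)

    def test_negative_counts_rejected(self):
        counts = -np.ones((4, 2))
        with pytest.raises(ValueError, match="negative"):
            build_pwm("m", counts)


class TestExactScoreNull:
    def test_width_one_single_base_tail(self):
        # log-odds [1,0,0,-1] under uniform background: P(score >= 1) = 1/4
        m = MotifModel("m", counts=np.ones((4, 1)),
                       pwm=np.array([[1.0], [0.0], [0.0], [-1.0]]),
                       background=np.full(4, 0.25))
        null = exact_score_null(m, grid_step=1e-3)
        assert null.pvalue_of_score(1.0) == pytest.approx(0.25)
        assert null.pvalue_of_score(0.0) == pytest.approx(0.75)

    def test_width_two_dinucleotide_tail(self):
        col = np.array([1.0, 0.0, 0.0, -1.0])
        m = MotifModel("m", counts=np.ones((4, 2)),
                       pwm=np.column_stack([col, col]),
                       background=np.full(4, 0.25))
        null = exact_score_null(m)
        # score 2 requires A at both positions: 1/16
        assert null.pvalue_of_score(2.0) == pytest.approx(0.0625)

    def test_total_mass_at_minimum(self):
        rng = np.random.default_rng(3)
        m = build_pwm("m", random_counts(rng, 5))
        null = exact_score_null(m)
        assert null.pvalue_of_int(null.min_total) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        """DP tail equals brute-force enumeration over all 4^w words,
        exactly on the discretized grid (uniform background)."""
        rng = np.random.default_rng(seed)
        width = int(rng.integers(2, 7))
        m = build_pwm("m", random_counts(rng, width))
        null = exact_score_null(m)
        tail = enumerate_tail(null)
        for t, p in tail.items():
            assert null.pvalue_of_int(t) == p  # dyadic floats: exact

    def test_survival_function_non_increasing(self):
        rng = np.random.default_rng(9)
        m = build_pwm("m", random_counts(rng, 4))
        null = exact_score_null(m)
        assert np.all(np.diff(null.sf) <= 0)


class TestScanWindow:
    def test_no_hits_on_mismatched_sequence(self):
        counts = np.ones((4, 2))
        counts[3] = 97  # strong TT consensus
        m = build_pwm("m", counts)
        assert scan_window(m, "AAAA", 1e-4) == []

    def test_planted_consensus_is_found(self):
        rng = np.random.default_rng(4)
        counts = np.ones((4, 8))
        cons = rng.integers(0, 4, size=8)
        for j, b in enumerate(cons):
            counts[b, j] = 97
        m = build_pwm("m", counts)
        seq = "G" * 3 + m.consensus + "C" * 3
        hits = scan_window(m, seq, 1e-4)
        assert any(h.offset == 3 and h.strand == "+" for h in hits)
        # brute-force rescan: any other reported hit must also pass on recheck
        null = exact_score_null(m)
        for h in hits:
            if h.strand != "+":
                continue
            sub = seq[h.offset:h.offset + m.width]
            total = sum(null.int_pwm["ACGT".index(c), j]
                        for j, c in enumerate(sub))
            assert null.pvalue_of_int(int(total)) <= 1e-4

    def test_palindromic_motif_scores_both_strands_equally(self):
        counts = np.ones((4, 4))
        for j, b in enumerate("ACGT"):  # ACGT is its own reverse complement
            counts["ACGT".index(b), j] = 50
        m = build_pwm("m", counts)
        assert np.allclose(m.pwm, m.reverse_complement().pwm)
        hits = scan_window(m, "TTACGTTT", 1.0)
        by_strand = {s: sorted((h.offset, round(h.score, 6)) for h in hits
                               if h.strand == s) for s in "+-"}
        assert by_strand["+"] == by_strand["-"]

    def test_strand_consistency_with_reverse_complement(self):
        """Scanning S with M on - strand equals scanning revcomp(S) on +."""
        rng = np.random.default_rng(12)
        m = build_pwm("m", random_counts(rng, 5))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=15))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        minus = sorted(round(h.score, 9) for h in scan_window(m, seq, 1.0)
                       if h.strand == "-")
        plus_rc = sorted(round(h.score, 9) for h in scan_window(m, rc, 1.0)
                         if h.strand == "+")
        assert minus == plus_rc

    def test_short_sequence_returns_empty(self):
        m = build_pwm("m", np.ones((4, 6)))
        assert scan_window(m, "ACG", 0.5) == []

    def test_ambiguous_base_never_hits(self):
        counts = np.ones((4, 3))
        counts[0] = 97
        m = build_pwm("m", counts)
        assert scan_window(m, "ANA", 1.0) == []


class TestCallPerturbation:
    @staticmethod
    def _motif_with_consensus(cons):
        counts = np.ones((4, len(cons)))
        for j, c in enumerate(cons):
            counts["ACGT".index(c), j] = 97
        return build_pwm("m", counts)

    def test_risk_allele_completing_consensus_is_gained(self):
        m = self._motif_with_consensus("ACGTACG")
        w = m.width
        flank = "T" * (w - 1)
        center = w - 1
        base = flank + "?" + flank
        # plant the consensus starting at the SNP
        seq = list(base)
        seq[center + 1:center + w] = list("CGTACG")
        nonrisk = "".join(seq[:center]) + "T" + "".join(seq[center + 1:])
        risk = "".join(seq[:center]) + "A" + "".join(seq[center + 1:])
        call = call_perturbation(m, nonrisk, risk, 1e-4, rsid="rs1")
        assert call.status == "gained"
        # mirror: swap the windows and binding is lost
        assert call_perturbation(m, risk, nonrisk, 1e-4).status == "lost"

    def test_identical_windows_cannot_switch(self):
        m = self._motif_with_consensus("ACGTACG")
        seq = "T" * 6 + m.consensus
        call = call_perturbation(m, seq, seq, 1e-4)
        assert call.status in ("unchanged_bound", "unbound")

    def test_windows_differing_twice_rejected(self):
        m = self._motif_with_consensus("ACGT")
        with pytest.raises(ValueError, match="bi-allelic"):
            call_perturbation(m, "AAAAAAA", "TTAAAAA")

    def test_same_allele_in_both_windows_removes_the_call(self):
        """SNP attribution: a gained call disappears when both windows carry
        the same allele."""
        m = self._motif_with_consensus("ACGTACG")
        w = m.width
        center = w - 1
        seq = list("T" * (2 * w - 1))
        seq[center:center + w] = list(m.consensus)
        risk = "".join(seq)
        nonrisk = risk[:center] + "T" + risk[center + 1:]
        assert call_perturbation(m, nonrisk, risk, 1e-4).status == "gained"
        assert call_perturbation(m, risk, risk, 1e-4).status != "gained"

    @pytest.mark.parametrize("thresholds", [(1e-2, 1e-4)])
    def test_lowering_threshold_never_creates_binding(self, thresholds):
        loose, strict = thresholds
        rng = np.random.default_rng(21)
        m = self._motif_with_consensus("GATTACAA")
        w = m.width
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2 * w - 1))
            a1, a2 = "A", "C"
            center = w - 1
            w1 = seq[:center] + a1 + seq[center + 1:]
            w2 = seq[:center] + a2 + seq[center + 1:]
            at_loose = call_perturbation(m, w1, w2, loose).status
            at_strict = call_perturbation(m, w1, w2, strict).status
            if at_loose == "unbound":
                assert at_strict == "unbound"
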