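import itertools

import numpy as np
import pytest

from embryoexpress.errors import InputError
from embryoexpress.motifs import (PWM, expected_hit_frequency, hit_statistics,
                                  hits_to_frame, ic_ecdf, information_content,
                                  load_pwm, read_counts_tsv, read_meme,
                                  scan_sequences, score_pvalue_table)
from embryoexpress.sequences import ALPHABET, SequenceSet

from conftest import DATA_DIR, brute_force_pvalue, brute_force_word_scores


class TestLoadPWM:
    def test_counts_with_pseudocount(self):
        pwm = load_pwm(np.array([[4.0, 0, 0, 0]]), pseudocount=0.01)
        expected = np.array([4.01, 0.01, 0.01, 0.01]) / 4.04
        assert np.allclose(pwm.probs[0], expected)
        assert pwm.probs.sum() == pytest.approx(1.0)

    def test_probabilities_passthrough(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]])
        pwm = load_pwm(probs, pseudocount=0.0, kind="probabilities")
        assert np.allclose(pwm.probs, probs)

    def test_zero_column_without_pseudocount_rejected(self):
        with pytest.raises(InputError):
            load_pwm(np.array([[0.0, 0, 0, 0]]), pseudocount=0.0,
                     kind="counts")

    def test_negative_entries_rejected(self):
        with pytest.raises(InputError):
            load_pwm(np.array([[1.0, -1, 1, 1]]))

    def test_transposed_input_accepted(self):
        counts = np.random.default_rng(0).integers(1, 9, (4, 7)).astype(float)
        pwm = load_pwm(counts)
        assert len(pwm) == 7

    def test_bad_background_rejected(self):
        with pytest.raises(InputError):
            load_pwm(np.ones((3, 4)), background=[0.5, 0.5, 0.0, 0.0])


class TestInformationContent:
    def test_background_pwm_has_zero_bits(self):
        pwm = load_pwm(np.full((5, 4), 0.25), pseudocount=0.0,
                       kind="probabilities")
        assert information_content(pwm) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_six_mer_is_twelve_bits(self):
        eps = 1e-12
        probs = np.full((6, 4), eps / 3)
        probs[np.arange(6), [0, 1, 2, 3, 0, 1]] = 1.0 - eps
        pwm = PWM("onehot", probs / probs.sum(axis=1, keepdims=True))
        assert information_content(pwm) == pytest.approx(12.0, abs=1e-6)

    def test_two_binary_columns_are_two_bits(self):
        eps = 1e-9
        col = np.array([0.5 - eps, 0.5 - eps, eps, eps])
        pwm = PWM("half", np.stack([col / col.sum()] * 2))
        assert information_content(pwm) == pytest.approx(2.0, abs=1e-6)

    def test_additive_over_columns(self, fixture_pwms):
        pwm = fixture_pwms[0]
        per_col = [information_content(PWM("c", pwm.probs[i:i + 1],
                                           pwm.background))
                   for i in range(len(pwm))]
        assert information_content(pwm) == pytest.approx(sum(per_col))

    def test_nonnegative_for_all_fixtures(self, fixture_pwms):
        for pwm in fixture_pwms:
            assert information_content(pwm) >= 0.0


class TestExpectedHitFrequency:
    def test_zero_bits_gives_one(self):
        pwm = load_pwm(np.full((3, 4), 0.25), pseudocount=0.0,
                       kind="probabilities")
        assert expected_hit_frequency(pwm) == pytest.approx(1.0)

    def test_two_bits_gives_quarter(self):
        eps = 1e-12
        col = np.array([0.5 - eps, 0.5 - eps, eps, eps])
        pwm = PWM("x", np.stack([col / col.sum()] * 2))
        assert expected_hit_frequency(pwm) == pytest.approx(0.25, abs=1e-9)

    def test_strictly_decreasing_in_ic(self, fixture_pwms):
        pairs = sorted((information_content(p), expected_hit_frequency(p))
                       for p in fixture_pwms)
        freqs = [f for _, f in pairs]
        assert all(a > b for a, b in zip(freqs, freqs[1:]))

    def test_consensus_class_rate_tracks_2_to_minus_ic(self):
        # a ~6-bit 5-mer with quasi-Boolean columns (1 or 2 admissible
        # letters per position): the chance that background DNA spells an
        # all-admissible word stays within a factor of 2 of 2^-I
        admissible = [(0, 1), (2,), (0, 3), (1,), (2, 3)]   # I ~ 6 bits
        probs = np.full((5, 4), 0.01)
        for i, letters in enumerate(admissible):
            for n in letters:
                probs[i, n] = (1.0 - 0.01 * (4 - len(letters))) / len(letters)
        pwm = PWM("quasi", probs / probs.sum(axis=1, keepdims=True))
        ic = information_content(pwm)
        assert 5.0 < ic < 7.0
        # Monte-Carlo on 10^5 bp of i.i.d. background
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 4, 10 ** 5)
        win = np.lib.stride_tricks.sliding_window_view(seq, 5)
        match = np.ones(len(win), dtype=bool)
        for i, letters in enumerate(admissible):
            match &= np.isin(win[:, i], letters)
        rate = match.mean()
        assert 0.5 < rate / 2.0 ** (-ic) < 2.0


class TestICEcdf:
    def test_three_distinct_pwms(self, fixture_pwms):
        freqs, heights = ic_ecdf(fixture_pwms[:3])
        assert np.allclose(heights, [1 / 3, 2 / 3, 1.0])
        assert np.all(np.diff(freqs) >= 0)

    def test_duplicate_pwm_vertical_step(self, fixture_pwms):
        pwm = fixture_pwms[0]
        freqs, heights = ic_ecdf([pwm, pwm, fixture_pwms[1]])
        f0 = expected_hit_frequency(pwm)
        assert (np.isclose(freqs, f0)).sum() == 2
        assert heights[-1] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            ic_ecdf([])


class TestScorePvalueTable:
    def test_trimer_pvalues_match_enumeration(self):
        for trial in range(4):
            counts = np.random.default_rng(trial).integers(
                1, 50, (3, 4)).astype(float)
            pwm = load_pwm(counts, pseudocount=0.01)
            dist = score_pvalue_table(pwm, granularity=1000)
            scores, probs = brute_force_word_scores(pwm)
            # per-column rounding deviates by at most half a bin each
            bin_width = 3 * 0.5 / dist.scale
            for word in itertools.product(range(4), repeat=3):
                k = sum(dist.int_scores[i, w] for i, w in enumerate(word))
                s = sum(pwm.log_odds()[i, w] for i, w in enumerate(word))
                p_dp = float(dist.pvalue_int(k))
                p_lo = brute_force_pvalue(scores, probs, s + bin_width)
                p_hi = brute_force_pvalue(scores, probs, s - bin_width)
                assert p_lo - 1e-12 <= p_dp <= p_hi + 1e-12

    def test_extreme_scores(self, fixture_pwms):
        for pwm in fixture_pwms:
            dist = score_pvalue_table(pwm)
            kmax = int(dist.int_scores.max(axis=1).sum())
            consensus_bg = np.prod(
                pwm.background[np.argmax(pwm.probs, axis=1)])
            # p at the top integer score covers the consensus word plus any
            # words rounded into the same bin
            scores, probs = brute_force_word_scores(pwm)
            p_top = float(dist.pvalue_int(kmax))
            assert p_top >= consensus_bg * (1 - 1e-9)
            assert p_top <= brute_force_pvalue(
                scores, probs, scores.max() - len(pwm) / dist.scale) + 1e-12
            assert float(dist.pvalue_int(0)) == 1.0

    def test_granularity_floor(self, fixture_pwms):
        with pytest.raises(InputError):
            score_pvalue_table(fixture_pwms[0], granularity=50)


class TestScanSequences:
    def test_planted_consensus_found_on_plus_strand(self, fixture_pwms):
        pwm = next(p for p in fixture_pwms if p.name == "synth_sharp_w5")
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(ALPHABET), 60))
        seq = seq[:10] + pwm.consensus + seq[10 + len(pwm):]
        hits = scan_sequences(SequenceSet(records=[("s", seq)]), pwm,
                              p_threshold=0.001)
        assert any(h.start == 10 and h.end == 10 + len(pwm)
                   and h.strand == "+" for h in hits)

    def test_reverse_complement_mirrors_hits(self, fixture_pwms):
        pwm = fixture_pwms[3]
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list(ALPHABET), 500))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = scan_sequences(SequenceSet(records=[("s", seq)]), pwm,
                             p_threshold=0.01)
        rev = scan_sequences(SequenceSet(records=[("s", rc)]), pwm,
                             p_threshold=0.01)
        assert len(fwd) == len(rev)
        mirrored = sorted((len(seq) - h.end, len(seq) - h.start,
                           "+" if h.strand == "-" else "-") for h in rev)
        assert mirrored == sorted((h.start, h.end, h.strand) for h in fwd)

    def test_sequence_shorter_than_motif(self, fixture_pwms):
        pwm = fixture_pwms[3]                      # 8-mer
        hits = scan_sequences(SequenceSet(records=[("s", "ACGTAC")]), pwm)
        assert hits == []

    def test_ambiguous_window_voided(self, fixture_pwms):
        pwm = next(p for p in fixture_pwms if p.name == "synth_sharp_w5")
        seq = "TTTT" + pwm.consensus + "TTTT"
        clean = scan_sequences(SequenceSet(records=[("s", seq)]), pwm,
                               p_threshold=0.01)
        noisy = seq[:6] + "N" + seq[7:]
        # SequenceSet enforces ACGT, so scan a raw-records set bypassing it
        sset = SequenceSet(records=[("s", seq)])
        sset.records = [("s", noisy)]
        broken = scan_sequences(sset, pwm, p_threshold=0.01)
        assert any(h.start == 4 for h in clean)
        assert not any(h.start == 4 for h in broken)

    def test_exhaustive_oracle_equivalence(self, fixture_pwms):
        """Scan hits and p-values agree with 4^L enumeration for every
        fixture motif (all have L <= 8)."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(ALPHABET), 3000))
        sset = SequenceSet(records=[("s", seq)])
        codes = np.array([ALPHABET.index(b) for b in seq])
        for pwm in fixture_pwms:
            L = len(pwm)
            dist = score_pvalue_table(pwm, granularity=1000)
            scores, probs = brute_force_word_scores(pwm)
            order = np.argsort(scores)[::-1]
            sorted_scores = scores[order]
            tail = np.cumsum(probs[order])
            hits = scan_sequences(sset, pwm, p_threshold=0.01, strands="+")
            hit_starts = {h.start: h for h in hits}
            win = np.lib.stride_tricks.sliding_window_view(codes, L)
            lod = pwm.log_odds()
            true_scores = lod[np.arange(L)[None, :], win].sum(axis=1)
            bin_width = L * 0.5 / dist.scale
            for j, s in enumerate(true_scores):
                idx = np.searchsorted(-sorted_scores, -(s - 1e-9),
                                      side="right")
                p_true = tail[idx - 1] if idx > 0 else 0.0
                if j in hit_starts:
                    h = hit_starts[j]
                    assert h.score == pytest.approx(float(s), abs=1e-9)
                    p_lo = brute_force_pvalue(scores, probs, s + bin_width)
                    p_hi = brute_force_pvalue(scores, probs, s - bin_width)
                    assert p_lo - 1e-12 <= h.p <= p_hi + 1e-12
                else:
                    # non-hits must be above threshold allowing one bin
                    assert brute_force_pvalue(scores, probs,
                                              s - bin_width) > 0.01 - 1e-12


class TestHitStatistics:
    @staticmethod
    def _hits(pwm_name, spec):
        from embryoexpress.motifs import MotifHit

        return [MotifHit(seq_id=sid, start=s, end=s + 5, strand="+",
                         score=sc, p=0.0005, motif=pwm_name)
                for sid, s, sc in spec]

    def test_mean_hits_per_sequence(self):
        seqs = SequenceSet(records=[("a", "A" * 100), ("b", "A" * 50)])
        hits = self._hits("m", [("a", 0, 5.0), ("a", 10, 4.0),
                                ("a", 20, 3.0), ("b", 0, 6.0)])
        stats_ = hit_statistics(hits, seqs)
        assert stats_.per_sequence.loc["a", "m"] == 3
        assert stats_.per_sequence["m"].mean() == pytest.approx(2.0)

    def test_per_bp_normalization(self):
        seqs = SequenceSet(records=[("a", "A" * 100)])
        stats_ = hit_statistics(self._hits("m", [("a", 3, 5.0)]), seqs)
        assert stats_.per_bp.loc["a", "m"] == pytest.approx(0.01)

    def test_top_fraction_keeps_best_scores(self):
        seqs = SequenceSet(records=[("a", "A" * 100)])
        hits = self._hits("m", [("a", i, float(i)) for i in range(10)])
        stats_ = hit_statistics(hits, seqs, top_fraction=0.30)
        assert len(stats_.top_hits) == 3
        assert sorted(h.score for h in stats_.top_hits) == [7.0, 8.0, 9.0]

    def test_motif_set_averages(self):
        seqs = SequenceSet(records=[("a", "A" * 100), ("b", "A" * 100)])
        hits = (self._hits("m1", [("a", 0, 1.0), ("b", 0, 1.0)])
                + self._hits("m2", [("a", 5, 1.0)]))
        stats_ = hit_statistics(hits, seqs,
                                motif_sets={"early": ["m1", "m2"],
                                            "late": ["m1"]})
        assert stats_.set_averages["early"] == pytest.approx((1.0 + 0.5) / 2)
        assert stats_.set_averages["late"] == pytest.approx(1.0)

    def test_unknown_sequence_rejected(self):
        seqs = SequenceSet(records=[("a", "A" * 10)])
        with pytest.raises(InputError):
            hit_statistics(self._hits("m", [("zzz", 0, 1.0)]), seqs)


def test_counts_tsv_round_trip():
    pwm = read_counts_tsv(DATA_DIR / "synth_counts.tsv")
    assert len(pwm) == 6
    assert np.allclose(pwm.probs.sum(axis=1), 1.0)


def test_meme_round_trip(tmp_path, fixture_pwms):
    from embryoexpress.motifs import write_meme

    out = tmp_path / "x.meme"
    write_meme(fixture_pwms, out)
    back = read_meme(out)
    assert [p.name for p in back] == [p.name for p in fixture_pwms]
    for a, b in zip(fixture_pwms, back):
        assert np.abs(a.probs - b.probs).max() < 1e-3


def test_hits_frame_schema(fixture_pwms):
    pwm = fixture_pwms[0]
    seqs = SequenceSet(records=[("s", "ACGTACGTACGT")])
    df = hits_to_frame(scan_sequences(seqs, pwm, p_threshold=1.0))
    assert list(df.columns) == ["seq_id", "start", "end", "strand",
                                "score", "p", "motif"]
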