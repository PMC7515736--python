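"""PWM/TFFM training, scoring, scanning."""

import json

import numpy as np
import pytest

from seqdap.motifs import (
    PWM,
    TFFM1,
    encode,
    load_model,
    reverse_complement,
    scan_region,
    scan_scores,
    score_site,
    select_training_peaks,
    train_pwm,
    train_tffm,
)
from seqdap.pooling import ConsensusPeak
from seqdap.synthetic import default_carg_pwm, sample_from_pwm

from conftest import plant_in_background


@pytest.fixture(scope="module")
def strong_pwm(truth_pwm):
    return truth_pwm


class TestScoreSite:
    def test_background_model_scores_half(self):
        # model identical to background: LR = 1 everywhere -> s = 0.5
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        model = PWM(np.tile(bg, (16, 1)), bg)
        assert score_site(model, "ACGT" * 4, "+") == pytest.approx(0.5)

    def test_limits(self, strong_pwm):
        consensus = "".join("ACGT"[i] for i in strong_pwm.probs.argmax(axis=1))
        anti = reverse_complement(consensus)  # palindromic: also high
        assert score_site(strong_pwm, consensus) > 0.99
        weak = "G" * 16  # violates the A/T core and CC/GG edges
        assert score_site(strong_pwm, weak, "+") < 0.2

    def test_n_window_scores_zero(self, strong_pwm):
        assert score_site(strong_pwm, "ACGTN" + "A" * 11) == 0.0

    def test_wrong_length_rejected(self, strong_pwm):
        with pytest.raises(ValueError):
            score_site(strong_pwm, "ACGT")

    def test_pwm_score_matches_product_oracle(self, strong_pwm):
        """s = LR/(1+LR) with LR from an independent per-position product."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            window = "".join(rng.choice(list("ACGT"), 16))
            lr = 1.0
            for j, base in enumerate(window):
                b = "ACGT".index(base)
                lr *= strong_pwm.probs[j, b] / strong_pwm.background[b]
            expected = lr / (1 + lr)
            assert score_site(strong_pwm, window, "+") == pytest.approx(
                expected, abs=1e-12
            )


class TestScanRegion:
    def test_planted_consensus_found_at_offset(self, strong_pwm):
        rng = np.random.default_rng(4)
        consensus = "".join("ACGT"[i] for i in strong_pwm.probs.argmax(axis=1))
        bg = "".join(rng.choice(list("ACGT"), 120))
        seq = bg[:50] + consensus + bg[66:]
        best, hits = scan_region(strong_pwm, seq, threshold=0.9)
        assert best > 0.99
        assert any(h.offset == 50 for h in hits)

    def test_threshold_one_yields_no_hits(self, strong_pwm):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 200))
        _, hits = scan_region(strong_pwm, seq, threshold=1.0)
        assert hits == []

    def test_short_region_warns_and_returns_empty(self, strong_pwm):
        with pytest.warns(UserWarning):
            best, hits = scan_region(strong_pwm, "ACGT", 0.5)
        assert best == 0.0 and hits == []

    def test_hits_match_brute_force_rescan(self, strong_pwm):
        rng = np.random.default_rng(6)
        for k in range(50):
            seq = "".join(rng.choice(list("ACGT"), 80))
            if rng.random() < 0.5:  # sometimes plant an instance
                inst = sample_from_pwm(strong_pwm, rng)
                pos = int(rng.integers(0, 64))
                seq = seq[:pos] + inst + seq[pos + 16 :]
            _, hits = scan_region(strong_pwm, seq, threshold=0.6)
            expected = sum(
                max(
                    score_site(strong_pwm, seq[i : i + 16], "+"),
                    score_site(strong_pwm, seq[i : i + 16], "-"),
                )
                >= 0.6
                for i in range(len(seq) - 15)
            )
            assert len(hits) == expected

    @pytest.mark.parametrize("model_kind", ["pwm", "tffm"])
    def test_reverse_complement_invariance(self, model_kind, truth_pwm, truth_tffm):
        model = truth_pwm if model_kind == "pwm" else truth_tffm
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 100))
            fwd = scan_scores(model, seq)
            rev = scan_scores(model, reverse_complement(seq))
            np.testing.assert_allclose(fwd, rev[::-1], atol=1e-9)


class TestTrainPwm:
    def test_degenerate_identical_site_converges(self):
        rng = np.random.default_rng(9)
        mer = "GGCCAAATTTGGCCAA"
        seqs = []
        for _ in range(100):
            bg = "".join(rng.choice(list("ACGT"), 100))
            pos = int(rng.integers(0, 84))
            seqs.append(bg[:pos] + mer + bg[pos + 16 :])
        pwm = train_pwm(seqs, W=16, palindromic=False, seed=0, pseudocount=0.01)
        planted_probs = pwm.probs[np.arange(16), encode(mer)]
        assert planted_probs.min() >= 0.99

    def test_palindromic_output_is_own_reverse_complement(self):
        rng = np.random.default_rng(10)
        seqs = plant_in_background(default_carg_pwm(), 80, 80, rng)
        pwm = train_pwm(seqs, W=16, palindromic=True, seed=0)
        np.testing.assert_allclose(pwm.probs, pwm.probs[::-1, ::-1], atol=1e-12)

    def test_training_determinism(self):
        rng = np.random.default_rng(11)
        seqs = plant_in_background(default_carg_pwm(), 60, 60, rng)
        p1 = train_pwm(seqs, seed=3)
        p2 = train_pwm(seqs, seed=3)
        np.testing.assert_array_equal(p1.probs, p2.probs)

    def test_sequences_shorter_than_w_rejected(self):
        with pytest.raises(ValueError):
            train_pwm(["ACGT"], W=16)


class TestTrainTffm:
    def test_likelihood_non_decreasing(self, truth_pwm):
        rng = np.random.default_rng(12)
        seqs = [sample_from_pwm(truth_pwm, rng) for _ in range(150)]
        model = train_tffm(seqs, truth_pwm, seed=0, collapse_alpha=0)
        trace = model.training_ll_
        assert len(trace) >= 2
        assert all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))

    def test_empty_input_rejected(self, truth_pwm):
        with pytest.raises(ValueError):
            train_tffm([], truth_pwm)

    def test_rows_sum_to_one(self, truth_pwm):
        rng = np.random.default_rng(13)
        seqs = [sample_from_pwm(truth_pwm, rng) for _ in range(100)]
        model = train_tffm(seqs, truth_pwm, seed=0)
        np.testing.assert_allclose(model.transitions.sum(axis=2), 1.0, atol=1e-9)
        assert model.initial.sum() == pytest.approx(1.0)


class TestSelectTrainingPeaks:
    def _peaks(self, n, genome_len=500000):
        rng = np.random.default_rng(14)
        covs = rng.permutation(n).astype(float)
        return [
            ConsensusPeak("c", 300 + 450 * k, mean_norm_cov=float(covs[k]))
            for k in range(n)
        ]

    def test_top_n_selected(self):
        genome = {"c": "A" * 500000}
        seqs = select_training_peaks(self._peaks(1000), genome, n=600)
        assert len(seqs) == 600

    def test_fewer_than_n_warns(self):
        genome = {"c": "A" * 500000}
        with pytest.warns(UserWarning):
            seqs = select_training_peaks(self._peaks(300), genome, n=600)
        assert len(seqs) == 300

    def test_tie_break_deterministic(self):
        genome = {"c": "A" * 500000}
        peaks = [ConsensusPeak("c", 300 + 450 * k, mean_norm_cov=1.0) for k in range(20)]
        s1 = select_training_peaks(peaks, genome, n=10)
        s2 = select_training_peaks(list(reversed(peaks)), genome, n=10)
        assert s1 == s2

    def test_missing_genome_rejected(self):
        with pytest.raises(ValueError):
            select_training_peaks(self._peaks(5), {}, n=3)


class TestSerialization:
    def test_pwm_json_round_trip(self, truth_pwm):
        again = load_model_from_text(truth_pwm.to_json())
        np.testing.assert_array_equal(again.probs, truth_pwm.probs)

    def test_tffm_json_round_trip(self, truth_tffm):
        again = load_model_from_text(truth_tffm.to_json())
        np.testing.assert_array_equal(again.transitions, truth_tffm.transitions)

    def test_meme_export_header(self, truth_pwm):
        text = truth_pwm.to_meme("carg")
        assert "MOTIF carg" in text
        assert f"w= {truth_pwm.width}" in text
        rows = [l for l in text.splitlines() if l and l[0].isdigit()]
        assert len(rows) == truth_pwm.width


def load_model_from_text(text):
    kind = json.loads(text)["type"]
    return PWM.from_json(text) if kind == "pwm" else TFFM1.from_json(text)
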