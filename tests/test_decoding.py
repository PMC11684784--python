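import numpy as np
import pytest

from conftest import make_subject
from tonepredict.decoding import (
    ConfusionTensor,
    DecoderConfig,
    TimeGenMatrix,
    bias_score,
    cross_decode,
    cv_decode_random,
    group_average,
)
from tonepredict.simulate import EpochsContainer


def _const_tg(value, n=5, subject="s"):
    t = np.arange(n) / 100.0
    return TimeGenMatrix(
        acc=np.full((n, n), value), train_times_s=t, test_times_s=t,
        test_condition="random", subject_id=subject,
    )


class TestCvDecoding:
    def test_noiseless_epochs_decoded_perfectly_at_peak(self, noiseless_subject):
        _, _, epochs = noiseless_subject
        tc, tg, _ = cv_decode_random(epochs)
        peak = np.argmin(np.abs(epochs.times_s - 0.10))
        assert tc[peak] == pytest.approx(1.0)

    def test_diagonal_equals_timecourse(self, noisy_subject):
        _, _, epochs = noisy_subject
        tc, tg, _ = cv_decode_random(epochs)
        assert np.array_equal(tc, tg.diagonal())

    def test_permuted_labels_decode_at_chance(self, noisy_subject):
        _, _, epochs = noisy_subject
        rng = np.random.default_rng(0)
        sel = epochs.sound_trials("random")
        shuffled = EpochsContainer(
            data=sel.data, times_s=sel.times_s, labels=rng.permutation(sel.labels),
            condition=sel.condition, sfreq=sel.sfreq, subject_id=sel.subject_id,
        )
        tc, _, _ = cv_decode_random(shuffled)
        assert abs(tc.mean() - 0.25) < 0.03

    def test_deterministic_given_fold_seed(self, noisy_subject):
        _, _, epochs = noisy_subject
        cfg = DecoderConfig(train_window_s=(0.0, 0.2), fold_seed=4)
        a = cv_decode_random(epochs, cfg)[1].acc
        b = cv_decode_random(epochs, cfg)[1].acc
        assert np.array_equal(a, b)

    def test_stratification_error_when_class_too_rare(self, noisy_subject):
        _, _, epochs = noisy_subject
        sel = epochs.sound_trials("random")
        keep = np.flatnonzero(sel.labels == 0)[:3].tolist() + \
            np.flatnonzero(sel.labels != 0).tolist()
        few = sel.select(np.array(sorted(keep)))
        with pytest.raises(ValueError, match="stratification"):
            cv_decode_random(few, DecoderConfig(n_folds=5))


class TestCrossDecoding:
    def test_resubstitution_on_separable_data_is_perfect(self, noiseless_subject):
        _, _, epochs = noiseless_subject
        cfg = DecoderConfig(train_window_s=(0.08, 0.12))
        tg = cross_decode(epochs, epochs.sound_trials("random"), cfg)
        peak = np.argmin(np.abs(tg.test_times_s - 0.10))
        row = np.argmin(np.abs(tg.train_times_s - 0.10))
        assert tg.acc[row, peak] == pytest.approx(1.0)

    def test_shuffled_test_labels_give_chance(self, noisy_subject):
        _, _, epochs = noisy_subject
        rng = np.random.default_rng(1)
        te = epochs.sound_trials("ordered")
        shuffled = EpochsContainer(
            data=te.data, times_s=te.times_s, labels=rng.permutation(te.labels),
            condition=te.condition, sfreq=te.sfreq, subject_id=te.subject_id,
        )
        cfg = DecoderConfig(train_window_s=(0.05, 0.15))
        tg = cross_decode(epochs, shuffled, cfg)
        assert abs(tg.acc.mean() - 0.25) < 0.03

    def test_control_like_subject_decodes_below_chance_prestimulus(
        self, small_design, small_sensors, kernel, fast_decoder_cfg
    ):
        _, _, epochs = make_subject(
            small_design, small_sensors, kernel, alpha_pre=-0.4, snr=4.0, seed=5
        )
        tg = cross_decode(epochs, epochs.sound_trials("ordered"), fast_decoder_cfg)
        bump = (tg.test_times_s >= -0.43) & (tg.test_times_s <= -0.33)
        assert tg.acc[:, bump].mean() < 0.25

    def test_channel_mismatch_rejected(self, noisy_subject):
        _, _, epochs = noisy_subject
        fewer = EpochsContainer(
            data=epochs.data[:, :10, :], times_s=epochs.times_s, labels=epochs.labels,
            condition=epochs.condition, sfreq=epochs.sfreq, subject_id="x",
            is_omission=epochs.is_omission,
        )
        with pytest.raises(ValueError, match="channel"):
            cross_decode(epochs, fewer)

    def test_lda_decisions_match_closed_form_two_class_oracle(self):
        # <=20 trials, 2 channels, 3 time points, two classes, no shrinkage:
        # the per-timepoint decision must reproduce w = S^-1 (mu1 - mu0)
        rng = np.random.default_rng(7)
        n, T = 20, 3
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 2, T)) + y[:, None, None] * np.array([1.0, -0.5])[None, :, None]
        times = np.arange(T) / 100.0
        train = EpochsContainer(
            data=X, times_s=times, labels=y, condition=np.full(n, "random", dtype=object),
            sfreq=100.0, subject_id="a",
        )
        Xte = rng.normal(size=(12, 2, T))
        test = EpochsContainer(
            data=Xte, times_s=times, labels=np.zeros(12, dtype=int),
            condition=np.full(12, "ordered", dtype=object), sfreq=100.0, subject_id="a",
        )
        cfg = DecoderConfig(shrinkage=None)
        tg = cross_decode(train, test, cfg)
        for ti in range(T):
            Xt = X[:, :, ti]
            mu0, mu1 = Xt[y == 0].mean(0), Xt[y == 1].mean(0)
            S = 0.5 * (np.cov(Xt[y == 0].T, bias=True) + np.cov(Xt[y == 1].T, bias=True))
            w = np.linalg.solve(S, mu1 - mu0)
            b = -0.5 * (mu0 + mu1) @ w
            pred = (Xte[:, :, ti] @ w + b > 0).astype(int)
            # oracle accuracy against the all-zero labels equals 1 - mean(pred)
            assert tg.acc[ti, ti] == pytest.approx(1.0 - pred.mean())


class TestBiasScore:
    def _tensor(self, mats):
        counts = np.asarray(mats, dtype=float)
        return ConfusionTensor(counts=counts, test_times_s=np.arange(len(counts)) / 100.0)

    def test_identity_confusion_scores_zero(self):
        conf = self._tensor([np.eye(4) * 10])
        assert bias_score(conf)[0] == pytest.approx(0.0)

    def test_all_mass_on_successor_scores_one(self):
        conf = self._tensor([np.roll(np.eye(4), 1, axis=1) * 5])
        assert bias_score(conf)[0] == pytest.approx(1.0)

    def test_uniform_confusion_scores_zero(self):
        conf = self._tensor([np.full((4, 4), 3.0)])
        assert bias_score(conf)[0] == pytest.approx(0.0)

    def test_invariant_to_count_scaling(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 30, size=(5, 4, 4)).astype(float)
        a = bias_score(self._tensor(counts))
        b = bias_score(self._tensor(counts * 7.5))
        assert np.allclose(a, b)

    def test_noncyclic_variant_uses_strict_upper_diagonals(self):
        m = np.eye(4)
        m[0, 1] = 1.0  # true 0 -> predicted 1
        conf = self._tensor([m])
        cyc = bias_score(conf, cyclic=True)[0]
        noncyc = bias_score(conf, cyclic=False)[0]
        assert cyc != pytest.approx(noncyc)

    def test_requires_three_classes(self):
        conf = ConfusionTensor(counts=np.ones((1, 2, 2)), test_times_s=np.array([0.0]))
        with pytest.raises(ValueError):
            bias_score(conf)

    def test_empty_row_cannot_be_normalized(self):
        m = np.ones((4, 4))
        m[2] = 0.0
        conf = self._tensor([m])
        with pytest.raises(ValueError):
            bias_score(conf)


class TestGroupAverage:
    def test_single_subject_identity(self):
        tg = _const_tg(0.4)
        assert np.array_equal(group_average([tg]).acc, tg.acc)

    def test_mean_of_two_and_order_invariance(self):
        a, b = _const_tg(0.2), _const_tg(0.6)
        m1 = group_average([a, b]).acc
        m2 = group_average([b, a]).acc
        assert np.allclose(m1, 0.4) and np.array_equal(m1, m2)

    def test_axis_mismatch_rejected(self):
        a = _const_tg(0.2, n=5)
        b = _const_tg(0.2, n=6)
        with pytest.raises(ValueError):
            group_average([a, b])
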