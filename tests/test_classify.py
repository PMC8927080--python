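"""Epoch extraction, FFT band features, and the MERF classifier."""

import logging

import numpy as np
import pandas as pd
import pytest

from fogsync import classify
from fogsync.spectral import CLASSIFIER6
from fogsync.synthetic import SimConfig, generate_session


@pytest.fixture(scope="module")
def epoch_sessions():
    cfg = SimConfig(
        trial_duration=30.0,
        neural_rate_hz=1000.0,
        n_strip_contacts=2,
        n_depth_contacts=2,
        fog_episodes_per_trial=1,
        fog_duration_range=(7.0, 9.0),
        subject_effect_sd=0.0,
        seed=21,
    )
    return [generate_session(cfg, "S01", f"T{i:02d}")[0] for i in range(3)]


class TestExtractEpochs:
    def test_two_fog_four_nfog_per_trial(self, epoch_sessions):
        epochs = classify.extract_epochs(epoch_sessions, seed=1)
        assert len(epochs) == 3 * 6
        by_trial: dict = {}
        for e in epochs:
            by_trial.setdefault(e.trial_id, []).append(e.label)
        for labels in by_trial.values():
            assert sorted(labels) == ["FOG", "FOG", "nFOG", "nFOG", "nFOG", "nFOG"]

    def test_epochs_respect_annotation_and_guard(self, epoch_sessions):
        epochs = classify.extract_epochs(epoch_sessions, seed=2, guard_s=1.0)
        by_trial = {s.trial_id: s.annotation for s in epoch_sessions}
        for e in epochs:
            ann = by_trial[e.trial_id]
            if e.label == "FOG":
                assert any(a <= e.start and e.start + 2.0 <= b for a, b in ann.intervals)
            else:
                for a, b in ann.intervals:
                    assert e.start + 2.0 <= a - 1.0 + 1e-9 or e.start >= b + 1.0 - 1e-9

    def test_no_overlap_within_trial(self, epoch_sessions):
        epochs = classify.extract_epochs(epoch_sessions, seed=3)
        by_trial: dict = {}
        for e in epochs:
            by_trial.setdefault(e.trial_id, []).append((e.start, e.start + 2.0))
        for spans in by_trial.values():
            spans.sort()
            for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
                assert s1 >= e0 - 1e-9

    def test_trial_with_short_freezing_skipped(self):
        cfg = SimConfig(
            trial_duration=30.0,
            neural_rate_hz=1000.0,
            n_strip_contacts=2,
            n_depth_contacts=2,
            fog_episodes_per_trial=1,
            fog_duration_range=(3.0, 3.0),  # < 2 x 2 s epochs
            subject_effect_sd=0.0,
            seed=22,
        )
        session, _ = generate_session(cfg, "S01", "T01")
        assert classify.extract_epochs([session], seed=1) == []

    def test_same_seed_same_starts(self, epoch_sessions):
        a = classify.extract_epochs(epoch_sessions, seed=7)
        b = classify.extract_epochs(epoch_sessions, seed=7)
        assert [e.start for e in a] == [e.start for e in b]

    def test_depth_channel_selection(self, epoch_sessions):
        epochs = classify.extract_epochs(epoch_sessions, seed=1, channels="depth")
        assert all(
            lab.startswith(("RDepth", "LDepth")) for lab in epochs[0].channel_labels
        )


class TestEpochFeatures:
    rate = 1000.0

    def test_tone_concentrates_in_beta(self):
        t = np.arange(2000) / self.rate
        feats = classify.epoch_features(np.sin(2 * np.pi * 20.0 * t), self.rate)
        beta = feats[0, [b[0] for b in CLASSIFIER6.bands].index("beta")]
        others = np.delete(feats[0], [b[0] for b in CLASSIFIER6.bands].index("beta"))
        assert (beta >= 100 * others).all()

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        a = classify.epoch_features(x, self.rate)
        b = classify.epoch_features(2 * x, self.rate)
        np.testing.assert_allclose(b, 4 * a, rtol=1e-9)

    def test_white_noise_feature_proportional_to_bandwidth(self):
        """Flat spectrum: band power scales with the realized band width,
        i.e. the number of 512-point FFT bins whose centre falls in the band
        (nominal width is distorted for bands only 1-3 bins wide)."""
        rng = np.random.default_rng(1)
        acc = np.zeros(len(CLASSIFIER6.bands))
        for _ in range(100):
            acc += classify.epoch_features(rng.standard_normal(2000), self.rate)[0]
        bins = np.fft.rfftfreq(512, 1 / self.rate)
        n_bins = np.array(
            [((bins >= lo) & (bins < min(hi, 500.0))).sum() for _l, lo, hi in CLASSIFIER6]
        )
        # the delta band is the single bin adjacent to DC, where per-segment
        # mean removal depresses power; check the bands clear of that edge
        per_bin = (acc / n_bins)[1:]
        np.testing.assert_allclose(per_bin / per_bin.mean(), 1.0, rtol=0.10)

    def test_epoch_shorter_than_nfft_errors(self):
        with pytest.raises(ValueError, match="shorter than n_fft"):
            classify.epoch_features(np.zeros(100), self.rate)

    def test_identical_epochs_identical_features(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 2000))
        np.testing.assert_array_equal(
            classify.epoch_features(x, self.rate), classify.epoch_features(x.copy(), self.rate)
        )


def _tabular(n_subjects=8, per_subject=25, intercept_sd=0.0, seed=0):
    """Synthetic clustered features: label from one feature + subject intercept."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0, intercept_sd)
        for _ in range(per_subject):
            x = rng.standard_normal(3)
            latent = 0.8 * x[0] + b + 0.5 * rng.standard_normal()
            rows.append((f"S{s}", f"S{s}trial", "FOG" if latent > 0 else "nFOG", *x))
    df = pd.DataFrame(rows, columns=["subject_id", "trial_id", "label", "f__a", "f__b", "f__c"])
    X = df[["f__a", "f__b", "f__c"]].to_numpy()
    y = (df["label"] == "FOG").to_numpy(int)
    return df, X, y, df["subject_id"].to_numpy()


class TestMerf:
    def test_null_random_effect_recovered(self):
        _df, X, y, g = _tabular(intercept_sd=0.0, seed=3)
        model = classify.MerfClassifier(n_estimators=50, max_iter=10).fit(X, y, g)
        assert model.sigma2_b_ <= 0.1 * model.sigma2_e_

    def test_strong_intercepts_beat_plain_forest(self):
        """MERF >= plain forest accuracy on >= 80% of 50 replicates when the
        label depends heavily on the subject intercept."""
        from sklearn.ensemble import RandomForestRegressor

        wins = 0
        for rep in range(50):
            _df, X, y, g = _tabular(intercept_sd=2.0, seed=100 + rep)
            rng = np.random.default_rng(rep)
            test = rng.uniform(size=len(y)) < 0.3
            train = ~test
            merf = classify.MerfClassifier(n_estimators=30, max_iter=4, random_state=rep)
            merf.fit(X[train], y[train], g[train])
            acc_m = np.mean(merf.predict(X[test], g[test]) == y[test])
            rf = RandomForestRegressor(n_estimators=30, random_state=rep)
            rf.fit(X[train], y[train])
            acc_f = np.mean((rf.predict(X[test]) >= 0.5).astype(int) == y[test])
            wins += int(acc_m >= acc_f)
        assert wins >= 40

    def test_single_subject_degenerates_with_warning(self, caplog):
        _df, X, y, _g = _tabular(n_subjects=1, seed=4)
        g = np.array(["S0"] * len(y))
        with caplog.at_level(logging.WARNING, logger="fogsync.classify"):
            model = classify.MerfClassifier(n_estimators=20, max_iter=3).fit(X, y, g)
        assert model.sigma2_b_ == 0.0
        assert any("single subject" in r.message for r in caplog.records)

    def test_unseen_subject_gets_zero_intercept(self):
        _df, X, y, g = _tabular(seed=5)
        model = classify.MerfClassifier(n_estimators=20, max_iter=3).fit(X, y, g)
        s_known = model.predict_score(X[:5], g[:5])
        s_unknown = model.predict_score(X[:5], np.array(["NEW"] * 5))
        np.testing.assert_allclose(
            s_unknown, model.forest_.predict(X[:5]), rtol=1e-12
        )
        assert not np.allclose(s_known, s_unknown)

    def test_gll_trace_non_increasing_after_burn_in(self):
        _df, X, y, g = _tabular(intercept_sd=1.0, seed=6)
        model = classify.MerfClassifier(n_estimators=40, max_iter=8, tol=0.0).fit(X, y, g)
        trace = np.asarray(model.gll_trace_)
        assert len(trace) >= 3
        # tolerance-checked monotonicity: forest refits may wiggle slightly
        assert (np.diff(trace[1:]) <= 0.05 * np.abs(trace[1:-1])).all()


class TestEvaluate:
    @staticmethod
    def _table(intercept_sd=0.5, seed=0, n_subjects=6, trials_per_subject=4):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            b = rng.normal(0, intercept_sd)
            for t in range(trials_per_subject):
                for label, k in (("FOG", 2), ("nFOG", 4)):
                    for _ in range(k):
                        base = 1.0 if label == "FOG" else 0.0
                        x = base + b + 0.7 * rng.standard_normal(3)
                        rows.append(
                            (f"S{s}", f"S{s}T{t}", label, *np.power(10.0, x))
                        )
        return pd.DataFrame(
            rows, columns=["subject_id", "trial_id", "label", "c1__beta", "c1__gamma", "c1__hfo"]
        )

    def test_trial_groups_never_split(self):
        table = self._table()
        rng = np.random.default_rng(0)
        train, test = classify._trial_split(table, 0.7, rng)
        tr = set(table["trial_id"][train])
        te = set(table["trial_id"][test])
        assert tr.isdisjoint(te)
        assert tr | te == set(table["trial_id"])

    def test_signal_detected_and_permutation_p_valid(self):
        table = self._table(seed=1)
        res = classify.evaluate(
            table, n_permutations=40, seed=2, n_estimators=30, max_iter=2, cv_folds=3
        )
        assert res["auc"] > 0.5
        assert 1 / 41 <= res["permutation_p"] <= 1.0
        assert res["permutation_p"] < 0.1

    def test_zero_permutations_reports_none(self):
        res = classify.evaluate(
            self._table(seed=3), n_permutations=0, seed=1, n_estimators=20, max_iter=2, cv_folds=2
        )
        assert res["permutation_p"] is None
        assert 0.0 <= res["accuracy"] <= 1.0

    def test_permuted_labels_near_chance(self):
        """Destroying labels leaves test accuracy near the majority rate."""
        table = self._table(seed=4)
        rng = np.random.default_rng(5)
        table = table.assign(label=rng.permutation(table["label"].to_numpy()))
        res = classify.evaluate(
            table, n_permutations=0, seed=6, n_estimators=30, max_iter=2, cv_folds=2
        )
        n = res["n_test_epochs"]
        # binomial band around the 2/3 majority-class rate
        assert abs(res["accuracy"] - 2 / 3) < 3 * np.sqrt(2 / 9 / n) + 0.05
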