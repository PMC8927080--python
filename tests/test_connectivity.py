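"""Coherence estimator, surrogate nulls, cluster/band verdicts, contrasts."""

import numpy as np
import pytest
import scipy.signal

from fogsync import connectivity as cn
from fogsync.session import FogAnnotation

RATE = 1000.0


def _noise(n, seed):
    return np.random.default_rng(seed).standard_normal(n)


class TestCoherencePair:
    def test_self_coherence_is_one(self):
        x = _noise(8000, 0)
        res = cn.coherence_pair(x, x, RATE)
        np.testing.assert_allclose(res.coherence, 1.0, atol=1e-12)

    def test_bounded_in_unit_interval(self):
        for seed in range(5):
            res = cn.coherence_pair(_noise(6000, seed), _noise(6000, seed + 100), RATE)
            assert (res.coherence >= 0).all() and (res.coherence <= 1).all()

    @pytest.mark.parametrize("cx,cy", [(0.5, 1.0), (3.0, 0.01), (1e4, 1e-4)])
    def test_amplitude_scaling_invariance(self, cx, cy):
        x, y = _noise(6000, 1), _noise(6000, 2)
        a = cn.coherence_pair(x, y, RATE)
        b = cn.coherence_pair(cx * x, cy * y, RATE)
        np.testing.assert_allclose(a.coherence, b.coherence, rtol=1e-9)

    @pytest.mark.parametrize("freq", [10.0, 45.0, 170.0])
    def test_pure_delay_preserves_unit_coherence(self, freq):
        """A delay of a noiseless tone is a pure phase shift: coherence at the
        tone's frequency stays 1 to numerical accuracy."""
        t = np.arange(8000) / RATE
        x = np.sin(2 * np.pi * freq * t + 0.3)
        d = 37
        y = np.concatenate([x[d:], x[:d]])
        res = cn.coherence_pair(x, y, RATE)
        assert res.coherence[int(freq) - 1] == pytest.approx(1.0, abs=1e-6)

    def test_single_segment_errors(self):
        with pytest.raises(ValueError, match="2 segments"):
            cn.coherence_pair(_noise(1000, 0), _noise(1000, 1), RATE)

    def test_matches_brute_force_dft_oracle(self):
        """Segment spectra against an explicit-DFT Welch implementation."""
        x, y = _noise(2048, 4), _noise(2048, 5)
        seg, ov = 1024, 0.5
        res = cn.coherence_pair(
            x, y, RATE, segment_s=seg / RATE, overlap=ov, freq_grid=np.arange(10, 400, 10.0)
        )
        # oracle: three half-overlapping Hann segments, explicit DFT
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(seg) / seg)
        dft = np.exp(-2j * np.pi * np.outer(np.arange(seg // 2 + 1), np.arange(seg)) / seg)
        Sxy = 0
        Sxx = 0
        Syy = 0
        for s in range(0, 2048 - seg + 1, seg // 2):
            xs = x[s : s + seg] - x[s : s + seg].mean()
            ys = y[s : s + seg] - y[s : s + seg].mean()
            Fx, Fy = dft @ (w * xs), dft @ (w * ys)
            Sxy = Sxy + Fx * np.conj(Fy)
            Sxx = Sxx + np.abs(Fx) ** 2
            Syy = Syy + np.abs(Fy) ** 2
        coh = np.abs(Sxy) / np.sqrt(Sxx * Syy)
        freqs = np.arange(seg // 2 + 1) * RATE / seg
        expected = np.interp(np.arange(10, 400, 10.0), freqs, coh)
        np.testing.assert_allclose(res.coherence, expected, rtol=1e-9, atol=1e-12)

    def test_independent_noise_bias_matches_simulation_oracle(self):
        """Mean coherence of independent noise sits at the estimator's K-segment
        bias level, checked against a direct small-n simulation."""
        K_target = 7
        n = 4000  # 1 s segments, 50% overlap -> 7 segments
        grid = np.arange(10.0, 200.0, 10.0)
        obs = cn.coherence_pair(_noise(n, 10), _noise(n, 11), RATE, freq_grid=grid)
        assert obs.n_segments == K_target
        rng = np.random.default_rng(12)
        sims = []
        for _ in range(400):
            r = cn.coherence_pair(
                rng.standard_normal(n), rng.standard_normal(n), RATE, freq_grid=grid
            )
            sims.append(r.coherence.mean())
        sims = np.asarray(sims)
        se = sims.std(ddof=1) * np.sqrt(1 + 1.0 / len(sims))
        assert abs(obs.coherence.mean() - sims.mean()) < 3 * se

    def test_squared_flag_squares(self):
        x, y = _noise(6000, 6), _noise(6000, 7)
        a = cn.coherence_pair(x, y, RATE)
        b = cn.coherence_pair(x, y, RATE, squared=True)
        np.testing.assert_allclose(b.coherence, a.coherence**2, rtol=1e-9)


class TestSurrogates:
    def _coupled(self, n=20000, seed=0, band=(23, 27)):
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1 / RATE)
        spec[(f < band[0]) | (f > band[1])] = 0
        src = np.fft.irfft(spec, n)
        src /= src.std()
        x = src + 0.5 * rng.standard_normal(n)
        y = src + 0.5 * rng.standard_normal(n)
        return x, y

    def test_seeded_null_is_reproducible(self):
        x, y = self._coupled(8000, 1)
        a = cn.shuffled_surrogates(x, y, RATE, n_surrogates=100, seed=5)
        b = cn.shuffled_surrogates(x, y, RATE, n_surrogates=100, seed=5)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("method", ["circular_shift", "segment_shuffle"])
    def test_coupled_band_exceeds_null_95th(self, method):
        x, y = self._coupled(20000, 2)
        res = cn.coherence_pair(x, y, RATE)
        null = cn.shuffled_surrogates(x, y, RATE, n_surrogates=100, method=method, seed=3)
        band = (res.frequencies >= 23) & (res.frequencies <= 27)
        q95 = np.quantile(null, 0.95, axis=0)
        assert (res.coherence[band] > q95[band]).all()

    def test_independent_pair_exceedance_near_alpha(self):
        """~5% of frequencies exceed the null 95th percentile under H0."""
        exceed = []
        for seed in range(10):
            x, y = _noise(20000, 200 + seed), _noise(20000, 300 + seed)
            res = cn.coherence_pair(x, y, RATE)
            null = cn.shuffled_surrogates(
                x, y, RATE, n_surrogates=100, method="segment_shuffle", seed=seed
            )
            q95 = np.quantile(null, 0.95, axis=0)
            exceed.append(np.mean(res.coherence > q95))
        rate = np.mean(exceed)
        # binomial CI at 10 runs x 200 frequencies (correlated across
        # neighbouring frequencies; allow a generous band around 0.05)
        assert 0.01 < rate < 0.12

    def test_short_shift_rejected(self):
        x, y = _noise(1500, 0), _noise(1500, 1)
        with pytest.raises(ValueError, match="too short"):
            cn.shuffled_surrogates(x, y, RATE, n_surrogates=100, method="circular_shift")


class TestBandSignificance:
    def _result_with_null(self, coupled: bool, seed=0):
        if coupled:
            rng = np.random.default_rng(seed)
            n = 20000
            white = rng.standard_normal(n)
            spec = np.fft.rfft(white)
            f = np.fft.rfftfreq(n, 1 / RATE)
            keep = ((f >= 23) & (f <= 27)) | ((f >= 165) & (f <= 175))
            spec[~keep] = 0
            src = np.fft.irfft(spec, n)
            src /= src.std()
            x = src + 0.7 * rng.standard_normal(n)
            y = src + 0.7 * rng.standard_normal(n)
        else:
            x, y = _noise(20000, seed + 50), _noise(20000, seed + 150)
        res = cn.coherence_pair(x, y, RATE, pair=("c", "d", "ipsi"))
        res.surrogate_null = cn.shuffled_surrogates(
            x, y, RATE, n_surrogates=200, method="segment_shuffle", seed=seed
        )
        return res

    def test_coupled_bands_significant_uncoupled_not(self):
        res = self._result_with_null(coupled=True, seed=1)
        verdicts = cn.band_significance([res]).set_index("band")
        assert verdicts.loc["high_beta", "significant"]
        assert verdicts.loc["high_gamma", "significant"]

    def test_alpha_one_makes_every_cluster_significant(self):
        res = self._result_with_null(coupled=True, seed=2)
        verdicts = cn.band_significance([res], alpha=1.0)
        assert verdicts["significant"].all()

    def test_missing_null_errors(self):
        res = cn.coherence_pair(_noise(4000, 0), _noise(4000, 1), RATE)
        with pytest.raises(ValueError, match="no surrogate null"):
            cn.band_significance([res])


class TestLaterality:
    @staticmethod
    def _res(level, side, seed):
        rng = np.random.default_rng(seed)
        coh = np.clip(level + 0.02 * rng.standard_normal(200), 0, 1)
        return cn.CoherenceResult(
            pair=("c", "d", side), frequencies=cn.FREQ_GRID.copy(), coherence=coh, n_segments=20
        )

    def test_swapping_sides_negates_t(self):
        trials = {
            f"T{i}": [self._res(0.6, "ipsi", i), self._res(0.4, "contra", 100 + i)]
            for i in range(6)
        }
        swapped = {
            t: [
                cn.CoherenceResult(
                    pair=(r.pair[0], r.pair[1], "contra" if r.pair[2] == "ipsi" else "ipsi"),
                    frequencies=r.frequencies,
                    coherence=r.coherence,
                    n_segments=r.n_segments,
                )
                for r in rs
            ]
            for t, rs in trials.items()
        }
        a = cn.laterality_contrast(trials)
        b = cn.laterality_contrast(swapped)
        assert b["t"] == pytest.approx(-a["t"], rel=1e-9)

    def test_missing_class_errors(self):
        trials = {"T0": [self._res(0.5, "ipsi", 0)]}
        with pytest.raises(ValueError, match="lacks a laterality class"):
            cn.laterality_contrast(trials)


class TestStateCoherence:
    def test_identical_states_give_zero_t(self):
        rng = np.random.default_rng(0)
        mk = lambda: cn.CoherenceResult(  # noqa: E731
            pair=("c", "d", "ipsi"),
            frequencies=cn.FREQ_GRID.copy(),
            coherence=np.clip(0.5 + 0.1 * rng.standard_normal(200), 0, 1),
            n_segments=10,
        )
        trials = []
        for _ in range(4):
            r = mk()
            trials.append({"FOG": r, "nonFOG": r})
        res = cn.state_coherence_contrast(trials)
        assert res["t"] == pytest.approx(0.0, abs=1e-12) or np.isnan(res["t"])

    def test_short_fog_yields_excluded_state(self):
        """Freezing shorter than two 1 s segments is excluded with a warning."""
        x, y = _noise(20000, 1), _noise(20000, 2)
        ann = FogAnnotation([(5.0, 6.4)])
        by_state = cn.coherence_by_state(x, y, RATE, ann)
        assert by_state["FOG"] is None
        assert by_state["nonFOG"] is not None

    def test_long_fog_contrast_detects_injected_difference(self):
        """Coupling present only during FOG is detected given many segments."""
        rng = np.random.default_rng(7)
        n = 60000  # 60 s, half FOG
        ann = FogAnnotation([(0.0, 30.0)])
        f = np.fft.rfftfreq(n, 1 / RATE)
        trials = []
        for i in range(5):
            spec = np.fft.rfft(rng.standard_normal(n))
            spec[(f < 23) | (f > 27)] = 0
            src = np.fft.irfft(spec, n)
            src /= src.std()
            gate = np.zeros(n)
            gate[: n // 2] = 1.0
            x = gate * src + 0.7 * rng.standard_normal(n)
            y = gate * src + 0.7 * rng.standard_normal(n)
            trials.append(cn.coherence_by_state(x, y, RATE, ann, trial_id=f"T{i}"))
        res = cn.state_coherence_contrast(trials, band=(23.0, 27.0))
        assert res["mean_fog"] > res["mean_nonfog"]
        assert res["p"] < 0.05
        assert all(k >= 2 for k in res["n_segments_fog"])
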