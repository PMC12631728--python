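import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipsim.scoring import (
    denoise,
    entropy_similarity,
    match_peaks,
    score_mvh,
    score_wdp,
    score_xcorr,
)
from sipsim.spectrum import Spectrum, StickSpectrum
from sipsim.synthetic import NoiseModel, make_observed, standard_theoretical


def brute_force_greedy(theoretical, observed, tolerance):
    """Independent reference for the matching rule, no vectorization tricks."""
    claimed = set()
    pairs = []
    for ti in sorted(range(len(theoretical)), key=lambda i: -theoretical.intensity[i]):
        candidates = [
            oi
            for oi in range(len(observed))
            if oi not in claimed and abs(observed.mz[oi] - theoretical.mz[ti]) <= tolerance
        ]
        if candidates:
            best = max(
                candidates,
                key=lambda oi: (observed.intensity[oi], -abs(observed.mz[oi] - theoretical.mz[ti])),
            )
            claimed.add(best)
            pairs.append((ti, best))
    return sorted(pairs)


class TestDenoise:
    def test_sparse_spectrum_unchanged(self):
        s = Spectrum(mz=[100.0, 300.0, 500.0], intensity=[1.0, 2.0, 3.0])
        out = denoise(s, window=100.0, top_n=10)
        assert out.mz == pytest.approx(s.mz)

    def test_single_survivor(self):
        mz = np.linspace(100, 110, 50)
        inten = np.ones(50)
        inten[25] = 1000.0
        out = denoise(Spectrum(mz=mz, intensity=inten), window=1000.0, top_n=1)
        assert len(out) == 1
        assert out.intensity[0] == 1000.0

    def test_retains_theoretical_sticks_over_noise(self):
        # 20 true sticks spread over the m/z range at SNR 10 against 200
        # exponential noise peaks; windowed top-10 filtering keeps >= 90%
        sticks = StickSpectrum(
            mz=np.linspace(150.0, 1900.0, 20), intensity=np.full(20, 100.0)
        )
        nm = NoiseModel(n_noise_peaks=200, noise_scale=10.0, peak_mz_sigma=0.0,
                        intensity_cv=0.0, seed=11)
        observed = make_observed(sticks, nm)
        out = denoise(observed, window=100.0, top_n=10)
        kept = match_peaks(sticks, out, tolerance=0.001)
        assert kept.n_matched >= 0.9 * len(sticks)

    def test_output_sorted(self):
        rng = np.random.default_rng(0)
        s = Spectrum(mz=rng.uniform(100, 1000, 300), intensity=rng.random(300))
        out = denoise(s, window=50.0, top_n=3)
        assert np.all(np.diff(out.mz) >= 0)


class TestMatchPeaks:
    def test_identity_match(self):
        theo = StickSpectrum(mz=[100.0, 101.0, 102.0], intensity=[50.0, 100.0, 20.0])
        obs = Spectrum(mz=theo.mz, intensity=theo.intensity)
        m = match_peaks(theo, obs, tolerance=0.01)
        assert m.n_matched == 3
        assert m.mz_errors == pytest.approx([0.0, 0.0, 0.0])
        assert m.unmatched_observed == []

    def test_shifted_beyond_tolerance(self):
        theo = StickSpectrum(mz=[100.0, 101.0], intensity=[100.0, 50.0])
        obs = Spectrum(mz=[100.02, 101.02], intensity=[100.0, 50.0])
        m = match_peaks(theo, obs, tolerance=0.01)
        assert m.n_matched == 0

    def test_more_intense_candidate_wins(self):
        theo = StickSpectrum(mz=[100.0], intensity=[100.0])
        obs = Spectrum(mz=[99.995, 100.004], intensity=[10.0, 50.0])
        m = match_peaks(theo, obs, tolerance=0.01)
        assert m.pairs == [(0, 1)]

    def test_intensity_tie_breaks_by_mz_error(self):
        theo = StickSpectrum(mz=[100.0], intensity=[100.0])
        obs = Spectrum(mz=[99.992, 100.003], intensity=[50.0, 50.0])
        m = match_peaks(theo, obs, tolerance=0.01)
        assert m.pairs == [(0, 1)]

    def test_each_observed_used_once(self):
        # overlapping windows force the greedy path
        theo = StickSpectrum(mz=[100.000, 100.005], intensity=[100.0, 90.0])
        obs = Spectrum(mz=[100.002], intensity=[5.0])
        m = match_peaks(theo, obs, tolerance=0.01)
        assert m.n_matched == 1
        assert m.pairs[0][0] == 0  # most intense theoretical stick claims it

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fast_path_matches_reference(self, seed):
        rng = np.random.default_rng(seed)
        theo = StickSpectrum(
            mz=np.cumsum(rng.uniform(0.5, 2.0, 8)) + 100.0,
            intensity=rng.uniform(1.0, 100.0, 8),
        )
        obs = Spectrum(
            mz=rng.uniform(98.0, 120.0, 40), intensity=rng.uniform(0.1, 100.0, 40)
        )
        m = match_peaks(theo, obs, tolerance=0.05)
        assert sorted(m.pairs) == brute_force_greedy(theo, obs, 0.05)


class TestWDP:
    def make_pair(self):
        envs = standard_theoretical(0.5)[:5]
        combined = StickSpectrum(
            mz=np.concatenate([e.mz for e in envs]),
            intensity=np.concatenate([e.intensity for e in envs]),
        )
        obs = Spectrum(mz=combined.mz, intensity=combined.intensity)
        return envs, obs

    def test_perfect_match_scores_one_per_envelope(self):
        envs, obs = self.make_pair()
        assert score_wdp(envs, obs) == pytest.approx(len(envs), abs=1e-9)

    def test_peak_removal_decreases_score(self):
        envs, obs = self.make_pair()
        full = score_wdp(envs, obs)
        reduced = Spectrum(mz=obs.mz[1:], intensity=obs.intensity[1:])
        assert score_wdp(envs, reduced) < full

    def test_empty_observed(self):
        envs, _ = self.make_pair()
        assert score_wdp(envs, Spectrum(mz=[], intensity=[])) == 0.0

    def test_scale_invariance(self):
        envs, obs = self.make_pair()
        doubled = Spectrum(mz=obs.mz, intensity=obs.intensity * 2.0)
        assert score_wdp(envs, doubled) == pytest.approx(score_wdp(envs, obs), rel=1e-12)

    def test_order_invariance(self):
        envs, obs = self.make_pair()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(obs))
        shuffled = Spectrum(mz=obs.mz[perm], intensity=obs.intensity[perm])
        assert score_wdp(envs, shuffled) == pytest.approx(score_wdp(envs, obs))


class TestXCorr:
    def test_uniform_observed_scores_zero(self):
        theo = StickSpectrum(mz=[500.0, 501.0], intensity=[100.0, 60.0])
        mz = np.arange(300.0, 700.0, 1.0005079)
        obs = Spectrum(mz=mz, intensity=np.full(mz.size, 10.0))
        assert abs(score_xcorr(theo, obs)) < 1e-6

    def test_identity_positive(self):
        theo = StickSpectrum(mz=[500.0, 501.0, 502.0], intensity=[100.0, 60.0, 20.0])
        obs = Spectrum(mz=theo.mz, intensity=theo.intensity)
        assert score_xcorr(theo, obs) > 0

    def test_intensity_scale_invariance(self):
        theo = StickSpectrum(mz=[500.0, 501.0, 502.0], intensity=[100.0, 60.0, 20.0])
        rng = np.random.default_rng(2)
        obs_mz = np.sort(rng.uniform(300, 700, 100))
        obs_int = rng.exponential(10.0, 100)
        a = score_xcorr(theo, Spectrum(mz=obs_mz, intensity=obs_int))
        b = score_xcorr(theo, Spectrum(mz=obs_mz, intensity=obs_int * 2.0))
        assert a == pytest.approx(b, rel=1e-9)


class TestMVH:
    def test_worked_hypergeometric_value(self):
        # 10 candidate bins, 4 observed-peak bins (one class), 4 theoretical
        # sticks, 2 matched: P = C(4,2) C(6,2) / C(10,4) = 90/210
        theo = StickSpectrum(
            mz=[100.0, 110.0, 120.0, 130.0], intensity=[100.0, 80.0, 60.0, 40.0]
        )
        obs = Spectrum(
            mz=[100.0, 110.0, 150.0, 160.0], intensity=[50.0, 40.0, 30.0, 20.0]
        )
        score = score_mvh(theo, obs, n_classes=1, tolerance=0.01, n_bins=10)
        assert score == pytest.approx(-math.log(90.0 / 210.0), abs=1e-9)

    def test_no_theoretical_sticks(self):
        obs = Spectrum(mz=[100.0], intensity=[1.0])
        assert score_mvh(StickSpectrum(mz=[], intensity=[]), obs) == 0.0

    def test_concentrated_matches_beat_scattered(self):
        # 9 observed peaks in 3 intensity classes; 3 sticks matching the top
        # class only vs one stick per class
        obs = Spectrum(
            mz=[100.0, 110.0, 120.0, 130.0, 140.0, 150.0, 160.0, 170.0, 180.0],
            intensity=[90.0, 85.0, 80.0, 50.0, 45.0, 40.0, 10.0, 8.0, 6.0],
        )
        concentrated = StickSpectrum(mz=[100.0, 110.0, 120.0], intensity=[1.0] * 3)
        scattered = StickSpectrum(mz=[100.0, 130.0, 160.0], intensity=[1.0] * 3)
        s_conc = score_mvh(concentrated, obs, n_classes=3, n_bins=100)
        s_scat = score_mvh(scattered, obs, n_classes=3, n_bins=100)
        assert s_conc > s_scat

    def test_scale_and_order_invariance(self):
        theo = StickSpectrum(mz=[100.0, 110.0, 120.0], intensity=[100.0, 50.0, 25.0])
        rng = np.random.default_rng(3)
        mz = np.sort(rng.uniform(90, 200, 30))
        inten = rng.exponential(10, 30)
        base = score_mvh(theo, Spectrum(mz=mz, intensity=inten), n_bins=200)
        perm = rng.permutation(30)
        assert score_mvh(
            theo, Spectrum(mz=mz[perm], intensity=inten[perm] * 7.0), n_bins=200
        ) == pytest.approx(base, abs=1e-12)


class TestEntropySimilarity:
    def test_identical_spectra(self):
        s = Spectrum(mz=[100.0, 200.0, 300.0], intensity=[1.0, 2.0, 3.0])
        assert entropy_similarity(s, s) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_single_peaks(self):
        a = Spectrum(mz=[100.0], intensity=[1.0])
        b = Spectrum(mz=[200.0], intensity=[1.0])
        # closed form: S_a = S_b = 0, S_mix = ln 2 -> 1 - 2 ln2/ln4 = 0
        assert entropy_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a = Spectrum(mz=np.sort(rng.uniform(100, 500, 20)), intensity=rng.random(20))
        b = Spectrum(mz=np.sort(rng.uniform(100, 500, 25)), intensity=rng.random(25))
        assert entropy_similarity(a, b) == pytest.approx(entropy_similarity(b, a), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 30), st.integers(1, 30))
    def test_bounded_in_unit_interval(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = Spectrum(mz=rng.uniform(100, 1000, na), intensity=rng.random(na) + 1e-9)
        b = Spectrum(mz=rng.uniform(100, 1000, nb), intensity=rng.random(nb) + 1e-9)
        assert 0.0 <= entropy_similarity(a, b) <= 1.0
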