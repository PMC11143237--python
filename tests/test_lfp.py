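"""Bipolar referencing, trial creation, tapers, multitaper power, tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import matmul_toeplitz

from chemofc import lfp


def _session(signal, layout, fs=1000.0, injection_s=1.0):
    return lfp.LfpSession(signal=signal, fs=fs, layout=layout,
                          injection_s=injection_s, condition="DCZ")


class TestBipolarReference:
    def test_identical_contacts_give_zero_site(self):
        x = np.random.default_rng(0).standard_normal(2000)
        s = _session(np.stack([x, x]), {"a": [0, 1]})
        bip = lfp.bipolar_reference(s)
        assert np.allclose(bip.data, 0.0)

    def test_contact_minus_zero_is_contact(self):
        x = np.random.default_rng(1).standard_normal(2000)
        s = _session(np.stack([x, np.zeros_like(x)]), {"a": [0, 1]})
        bip = lfp.bipolar_reference(s)
        assert np.allclose(bip.data[0], x)

    def test_sixteen_contacts_give_fifteen_sites(self):
        sig = np.random.default_rng(2).standard_normal((16, 2000))
        bip = lfp.bipolar_reference(_session(sig, {"a": list(range(16))}))
        assert bip.data.shape[0] == 15

    def test_common_mode_rejection(self):
        # any signal added to every contact of an array cancels exactly
        rng = np.random.default_rng(3)
        sig = rng.standard_normal((4, 2000))
        common = rng.standard_normal(2000)
        s1 = _session(sig, {"a": [0, 1, 2, 3]})
        s2 = _session(sig + common, {"a": [0, 1, 2, 3]})
        assert np.allclose(lfp.bipolar_reference(s1).data,
                           lfp.bipolar_reference(s2).data)

    def test_single_contact_array_rejected(self):
        sig = np.random.default_rng(4).standard_normal((1, 2000))
        with pytest.raises(lfp.LfpError, match="a"):
            lfp.bipolar_reference(_session(sig, {"a": [0]}))


class TestRejectSites:
    def _bipolar(self, rng, n_sites=8, n=20000):
        data = rng.standard_normal((n_sites, n))
        return lfp.BipolarSignal(data=data, fs=1000.0,
                                 sites=[("a", i) for i in range(n_sites)],
                                 source_contacts=[(i, i + 1)
                                                  for i in range(n_sites)],
                                 site_mask=np.ones(n_sites, dtype=bool))

    def test_clean_session_keeps_all_sites(self):
        bip = self._bipolar(np.random.default_rng(0))
        assert lfp.reject_sites(bip).site_mask.all()

    def test_high_amplitude_site_rejected(self):
        # one site replaced by 20x RMS broadband noise fails the RMS rule
        bip = self._bipolar(np.random.default_rng(1))
        bip.data[3] *= 20.0
        out = lfp.reject_sites(bip)
        assert not out.site_mask[3]
        assert out.site_mask.sum() == 7

    def test_line_contaminated_site_rejected(self):
        bip = self._bipolar(np.random.default_rng(2))
        t = np.arange(bip.data.shape[1]) / bip.fs
        bip.data[5] += 3.0 * np.sin(2 * np.pi * 60.0 * t)
        assert not lfp.reject_sites(bip).site_mask[5]

    def test_all_rejected_is_an_error(self):
        bip = self._bipolar(np.random.default_rng(3), n_sites=2)
        bip.site_mask[:] = False
        with pytest.raises(lfp.LfpError, match="all"):
            lfp.reject_sites(bip)


class TestTrialCreation:
    def _bip(self, dur_s=900.0):
        n = int(dur_s * 1000)
        data = np.random.default_rng(0).standard_normal((2, n))
        return lfp.BipolarSignal(data=data, fs=1000.0,
                                 sites=[("a", 0), ("a", 1)],
                                 source_contacts=[(0, 1), (1, 2)],
                                 site_mask=np.ones(2, dtype=bool))

    def test_fifty_disjoint_trials_from_600s_period(self):
        periods = lfp.PeriodDefinition(pre=(0.0, 600.0), post=(600.0, 900.0),
                                       waiting_s=0.0)
        ts = lfp.make_trialset(self._bip(), periods, "pre", 0, seed=1)
        assert ts.trials.shape == (50, 2, 4000)
        assert len(np.unique(ts.slot_indices)) == 50
        assert ts.slot_indices.max() < 150

    def test_same_seed_same_slots(self):
        periods = lfp.PeriodDefinition(pre=(0.0, 600.0), post=(600.0, 900.0),
                                       waiting_s=0.0)
        a = lfp.make_trialset(self._bip(), periods, "pre", 3, seed=9)
        b = lfp.make_trialset(self._bip(), periods, "pre", 3, seed=9)
        assert np.array_equal(a.slot_indices, b.slot_indices)
        c = lfp.make_trialset(self._bip(), periods, "pre", 4, seed=9)
        assert not np.array_equal(a.slot_indices, c.slot_indices)

    def test_repetitions_cover_the_slot_grid(self):
        # over 100 repetitions nearly every slot of a 1200-s period is used
        n_slots = 300
        used = np.zeros(n_slots, dtype=bool)
        for rep in range(100):
            used[lfp.repetition_slot_indices(n_slots, 50, rep, seed=5)] = True
        # coupon-collector: P(slot never chosen) = (1 - 1/6)^100 ~ 1.2e-8
        assert used.mean() > 0.95

    def test_short_period_is_an_error(self):
        periods = lfp.PeriodDefinition(pre=(0.0, 150.0), post=(150.0, 900.0),
                                       waiting_s=0.0)
        with pytest.raises(lfp.LfpError, match="slots"):
            lfp.make_trialset(self._bip(), periods, "pre", 0, seed=1)


class TestDpssTapers:
    def test_seven_tapers_for_4s_1hz(self, tapers):
        assert tapers.n_tapers == 7
        assert tapers.tapers.shape == (7, 4000)

    def test_orthonormality(self, tapers):
        gram = tapers.tapers @ tapers.tapers.T
        assert np.abs(gram - np.eye(7)).max() < 1e-8

    def test_first_taper_concentration_matches_direct_eigenvalue(self, tapers):
        # lambda = v' A v with the Toeplitz concentration kernel
        # A_jk = sin(2 pi W (j-k)) / (pi (j-k)), W = 1/1000 cycles/sample
        n = 4000
        w = 1.0 / 1000.0
        k = np.arange(n)
        col = np.empty(n)
        col[0] = 2 * w
        col[1:] = np.sin(2 * np.pi * w * k[1:]) / (np.pi * k[1:])
        v = tapers.tapers[0]
        lam = float(v @ matmul_toeplitz(col, v))
        assert lam > 0.99
        assert abs(lam - tapers.eigenvalues[0]) < 1e-6


class TestMultitaperSpectra:
    def test_white_noise_power_is_flat(self, tapers):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((120, 1, 4000))
        est = lfp.multitaper_spectra(trials, tapers)
        psd = est.power()[0]
        sel = (est.freqs >= 10) & (est.freqs <= 90)
        assert np.ptp(psd[sel]) / psd[sel].mean() < 0.10 * 3
        assert abs(psd[sel].mean() - 2.0 / 1000.0) / (2.0 / 1000.0) < 0.05

    def test_sinusoid_peaks_at_its_bin(self, tapers):
        t = np.arange(4000) / 1000.0
        trials = np.sin(2 * np.pi * 10.0 * t)[None, None, :].repeat(3, axis=0)
        est = lfp.multitaper_spectra(trials, tapers)
        assert est.freqs[np.argmax(est.power()[0])] == 10.0

    def test_parseval_band_power_matches_variance(self, tapers):
        # band-limited signal: integrated PSD ~ time-domain variance
        rng = np.random.default_rng(1)
        trials = lfp.apply_filters(
            rng.standard_normal((60, 1, 4096))[..., :4000], 1000.0,
            band=(5.0, 95.0))
        est = lfp.multitaper_spectra(trials, tapers)
        band_power = est.power()[0].sum() * 0.5    # df = 0.5 Hz
        variance = trials.var()
        assert abs(band_power - variance) / variance < 0.05

    def test_nan_input_is_an_error(self, tapers):
        trials = np.zeros((2, 1, 4000))
        trials[0, 0, 5] = np.nan
        with pytest.raises(lfp.LfpError, match="NaN"):
            lfp.multitaper_spectra(trials, tapers)

    def test_power_invariant_to_sign_flip_and_trial_order(self, tapers):
        rng = np.random.default_rng(2)
        trials = rng.standard_normal((10, 2, 4000))
        a = lfp.multitaper_spectra(trials, tapers).power()
        b = lfp.multitaper_spectra(-trials[::-1], tapers).power()
        assert np.allclose(a, b)

    def test_psd_matches_independent_multitaper_implementation(self, tapers):
        # cross-check against mne's multitaper PSD on the same data
        mne_tf = pytest.importorskip("mne.time_frequency")
        rng = np.random.default_rng(7)
        data = rng.standard_normal((8, 4000))
        ours = lfp.multitaper_spectra(data[:, None, :], tapers).power()[0]
        psd, freqs = mne_tf.psd_array_multitaper(
            data, sfreq=1000.0, bandwidth=2.0, adaptive=False,
            normalization="full", verbose=False)
        sel = np.isin(freqs, np.arange(1.0, 100.25, 0.5))
        ref = psd.mean(axis=0)[sel]
        assert ref.shape == ours.shape
        assert np.allclose(ours, ref, rtol=1e-2)

    def test_slot_cache_matches_direct_transform(self, tapers):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 40000))
        window = (0.0, 40.0)
        cache = lfp.slot_fourier(data, 1000.0, window, tapers)
        starts = lfp.slot_grid(window, 1000.0)
        direct = lfp.multitaper_spectra(
            np.stack([data[:, s:s + 4000] for s in starts]).astype(np.float32),
            tapers)
        assert np.allclose(cache, direct.fourier, rtol=1e-4, atol=1e-5)


class TestNormalizedPower:
    def test_identical_periods_give_zero(self):
        reps = np.random.default_rng(0).uniform(1, 2, (100, 3, 10))
        # post equal to the pre mean z-scores to exactly zero
        same = lfp.normalized_power_change(reps, reps.mean(0)[None])
        assert np.allclose(same.z, 0.0, atol=1e-12)
        # post drawn from the pre distribution averages to ~zero
        out = lfp.normalized_power_change(reps, reps)
        assert np.abs(out.z).max() < 1e-10

    def test_doubled_power_with_10pct_cv_gives_z_10(self):
        rng = np.random.default_rng(1)
        mu = 4.0
        pre = rng.normal(mu, 0.1 * mu, size=(4000, 1, 1))
        post = np.full((1, 1, 1), 2 * mu)
        out = lfp.normalized_power_change(pre, post)
        assert abs(out.z[0, 0] - 10.0) < 0.5

    def test_zero_pre_sd_names_the_bin(self):
        pre = np.ones((10, 1, 3))
        with pytest.raises(lfp.LfpError, match="bin 0"):
            lfp.normalized_power_change(pre, pre)


class TestPerBinTests:
    def test_all_positive_shifts_are_significant(self):
        vals = np.abs(np.random.default_rng(0).standard_normal((20, 4))) + 0.1
        p = lfp.per_bin_tests(vals)
        # exact signed-rank: all-positive n=20 gives p = 2 * 2^-20
        assert np.all(p < 1e-3)
        assert np.allclose(p, 2 * 2.0 ** -20)

    def test_symmetric_null_gives_uniformish_p(self):
        vals = np.random.default_rng(1).standard_normal((40, 199))
        p = lfp.per_bin_tests(vals)
        assert 0.3 < np.median(p) < 0.7

    def test_identical_groups_kruskal_p_one(self):
        g = np.ones((10, 5))
        with pytest.warns(UserWarning, match="tied"):
            p = lfp.per_bin_tests(None, test="kruskal", groups=[g, g])
        assert np.allclose(p, 1.0)

    def test_too_few_observations_error(self):
        with pytest.raises(lfp.LfpError):
            lfp.per_bin_tests(np.ones((4, 3)))


class TestConsecutiveSignificance:
    def test_five_bin_run_is_marked(self):
        p = np.array([.005] * 5 + [.5] * 5)
        mask = lfp.consecutive_significance(p)
        assert mask[:5].all() and not mask[5:].any()

    def test_four_bin_run_is_not_marked(self):
        p = np.array([.005] * 4 + [.5] * 6)
        assert not lfp.consecutive_significance(p).any()

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=199)
        strict = lfp.consecutive_significance(p, alpha=0.005)
        loose = lfp.consecutive_significance(p, alpha=0.05)
        assert not np.any(strict & ~loose)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60),
           st.floats(min_value=1e-6, max_value=0.5),
           st.integers(min_value=1, max_value=8))
    def test_matches_brute_force_run_rule(self, p, alpha, run_length):
        p = np.asarray(p)
        mask = lfp.consecutive_significance(p, alpha=alpha,
                                            run_length=run_length)
        # oracle: a bin is significant iff some window of run_length
        # consecutive bins containing it is entirely below alpha
        below = p < alpha
        expect = np.zeros_like(below)
        for i in range(len(p) - run_length + 1):
            if below[i:i + run_length].all():
                expect[i:i + run_length] = True
        assert np.array_equal(mask, expect)

    def test_familywise_rate_under_uniform_null(self):
        # 10^4 draws of 199 iid uniform p-values: P(any 5-run < .01) < .01
        rng = np.random.default_rng(3)
        below = rng.uniform(size=(10_000, 199)) < 0.01
        kernel = np.ones(5)
        runs = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="valid").max(), 1,
            below.astype(float))
        assert (runs >= 5).mean() < 0.01
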