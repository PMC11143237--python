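"""Reduced-scale calibration and recovery experiments.

These drive the full analysis chain on synthetic sessions with known
ground truth: null calibration of the coherency significance procedure,
band-of-interest recovery, modulation-criterion calibration, and rs-FC
difference-of-differences recovery.  Problem sizes are desk-scale
(documented in the methods note); the statistical structure matches the
full-scale design.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, norm

from . import coherency as coh
from . import lfp, rsfc, spikes, synth

#: reduced-scale session used for the 100-session null calibration
NULL_CFG = dict(contacts_per_array=4,
                period_durations=dict(pre=240.0, waiting=30.0, post=240.0))
#: reduced-scale session used for band recovery (longer periods, more sites)
BAND_CFG = dict(contacts_per_array=6,
                period_durations=dict(pre=600.0, waiting=60.0, post=600.0))


def _analyze_session(cfg, cond, plan, n_repetitions, seed):
    sess, truth = synth.generate_lfp_session(cfg, cond, plan)
    bip = lfp.reject_sites(lfp.bipolar_reference(sess))
    filt = lfp.apply_filters(bip.accepted(), sess.fs)
    d = cfg.period_durations
    periods = lfp.PeriodDefinition.from_injection(
        sess.injection_s, cond, pre_s=d["pre"], post_s=d["post"],
        waiting_s=d["waiting"])
    res = coh.session_coherency(bip, periods, n_repetitions=n_repetitions,
                                seed=seed, filtered=filt)
    amy, vl = coh.inter_areal_pairs(res.site_arrays)
    obs = [res.observed[p] for p in ("pre", "post")]
    nul = [res.null[p] for p in ("pre", "post")]
    p, mask = coh.coherency_significance(obs, nul, amy, vl)
    profile = np.mean([o.icoh[np.ix_(amy, vl)].mean(axis=(0, 1))
                       for o in obs], axis=0)
    return dict(p=p, mask=mask, profile=profile, freqs=res.freqs,
                truth=truth)


def null_calibration(n_sessions: int = 100, seed: int = 0,
                     n_repetitions: int = 8) -> dict:
    """Uncoupled sessions through the full significance procedure.

    Returns the fraction of sessions in which any band is declared
    (target: at most the nominal rate) and the per-session signed-rank
    p at a reference bin for exchangeability checks.
    """
    declared = 0
    p_ref, diff_ref = [], []
    ref_bin = None
    for i in range(n_sessions):
        cfg = synth.SynthConfig(seed=seed + i, coupling_gain=0.0, **NULL_CFG)
        out = _analyze_session(cfg, "DCZ", {"pre": 0.0, "post": 0.0},
                               n_repetitions, seed + 10_000 + i)
        declared += bool(out["mask"].any())
        if ref_bin is None:
            ref_bin = int(np.argmin(np.abs(out["freqs"] - 20.0)))
        p_ref.append(float(out["p"][ref_bin]))
        diff_ref.append(float(out["profile"][ref_bin]))
    return dict(n_sessions=n_sessions, declared=declared,
                rate=declared / n_sessions, p_reference_bin=p_ref,
                mean_pair_diff_reference_bin=diff_ref)


def band_recovery(n_sessions: int = 50, seed: int = 0,
                  n_repetitions: int = 10) -> dict:
    """Coupled sessions (9-12 Hz, lag pi/4): band recovered within 0.5 Hz."""
    hits = 0
    peaks, lows, highs = [], [], []
    truth_band = None
    for i in range(n_sessions):
        cfg = synth.SynthConfig(seed=seed + i, **BAND_CFG)
        out = _analyze_session(cfg, "DCZ", synth.default_period_plan("DCZ"),
                               n_repetitions, seed + 20_000 + i)
        truth_band = out["truth"].true_band
        if not out["mask"].any():
            continue
        band = coh.extract_band(out["profile"], out["freqs"], out["mask"])
        peaks.append(band.peak_hz)
        lows.append(band.low_hz)
        highs.append(band.high_hz)
        lo, hi, peak = truth_band
        if (abs(band.low_hz - lo) <= 0.5 and abs(band.high_hz - hi) <= 0.5
                and abs(band.peak_hz - peak) <= 0.5):
            hits += 1
    return dict(n_sessions=n_sessions, hits=hits, rate=hits / n_sessions,
                truth_band=truth_band,
                mean_peak_hz=float(np.mean(peaks)) if peaks else np.nan,
                mean_low_hz=float(np.mean(lows)) if lows else np.nan,
                mean_high_hz=float(np.mean(highs)) if highs else np.nan)


def modulation_calibration(n_null_units: int = 2500,
                           n_step_units: int = 200, seed: int = 0) -> dict:
    """False-positive and detection rates of the modulation criterion.

    The null arm feeds the criterion i.i.d. standard-normal post-bin z
    (a known baseline), for which the exact false-positive probability
    is P(Binomial(40, 0.05) >= 4).  The detection arm uses Poisson units
    with a x2 rate step from a 5 Hz baseline under the standard windows.
    """
    rng = np.random.default_rng(seed)
    flags = 0
    for _ in range(n_null_units):
        series = spikes.FiringRateSeries(
            rate_pre=np.zeros(20), rate_post=np.zeros(40),
            z_pre=np.zeros(20), z_post=rng.standard_normal(40))
        flags += spikes.detect_modulation(series).modulated
    target = float(binom.sf(3, 40, 0.05))

    periods = lfp.PeriodDefinition.from_injection(600.0, "DCZ")
    detected = 0
    for _ in range(n_step_units):
        times = []
        for t0, t1, r in ((0.0, 600.0, 5.0), (600.0, 3300.0, 10.0)):
            k = rng.poisson(r * (t1 - t0))
            times.append(rng.uniform(t0, t1, k))
        series = spikes.bin_rates(np.sort(np.concatenate(times)), periods)
        out = spikes.detect_modulation(series)
        detected += out.modulated and out.direction == "increase"
    return dict(null_rate=flags / n_null_units, binomial_target=target,
                n_null_units=n_null_units,
                step_detection_rate=detected / n_step_units,
                n_step_units=n_step_units)


def connectome_recovery(seed: int = 0, n_sessions_per_condition: int = 2,
                        n_volumes: int = 300, n_runs: int = 3) -> dict:
    """DCZ vs vehicle connectome difference of differences.

    Recovers the generator's Fisher-z increment on the amygdala-vlPFC
    cell; the analytic CI uses Fisher variance 1/(n-3) per period map,
    four maps per session pair, averaged over session pairs.
    """
    cfg = synth.SynthConfig(seed=seed, n_volumes=n_volumes, n_runs=n_runs)
    dcz, veh = [], []
    truth = None
    for i in range(n_sessions_per_condition):
        s, t, atlas = synth.generate_bold_session(cfg, "DCZ", session_index=i)
        dcz.append(s)
        truth = t
        s, _, atlas = synth.generate_bold_session(cfg, "VEH", session_index=i)
        veh.append(s)
    diff, cmean, vmean, labels = rsfc.connectome_change(dcz, veh, atlas)
    i, j = labels.index(1), labels.index(2)         # amygdala_l, vlpfc_l
    expect = truth.true_delta_z[("amygdala_l", "vlpfc_l")]
    n = n_volumes * n_runs
    se = np.sqrt(4.0 / (n - 3) / n_sessions_per_condition)
    return dict(measured_dz=float(diff[i, j]), expected_dz=float(expect),
                se=float(se), n_timepoints=n,
                within_ci=bool(abs(diff[i, j] - expect)
                               < norm.ppf(0.9995) * se))


def cluster_boundary(n_timepoints: int = 900) -> dict:
    """Exact extent-threshold boundary: 30-voxel blob kept, 29 dropped."""
    dm = rsfc.DiffMap(z_diff=np.zeros((24, 24, 24)),
                      n_timepoints=n_timepoints)
    dm.z_diff[1:6, 1:4, 1:3] = 1.0                  # 30 voxels
    dm.z_diff[10:15, 10:13, 10:12] = 1.0
    dm.z_diff[14, 12, 11] = 0.0                     # 29 voxels
    out = rsfc.threshold_and_clusterize(dm)
    sizes = sorted(out.table["size"])
    return dict(retained_sizes=sizes,
                kept_30=30 in sizes, dropped_29=29 not in sizes)


def icoh_closed_form(lag: float = np.pi / 4, seed: int = 0) -> dict:
    """Unit-coherence sinusoids with a known lag: icoh = sin(lag)."""
    rng = np.random.default_rng(seed)
    tapers = lfp.dpss_tapers()
    t = np.arange(4000) / 1000.0
    trials = []
    for _ in range(50):
        ph = rng.uniform(0, 2 * np.pi)
        trials.append(np.stack([np.sin(2 * np.pi * 10 * t + ph),
                                np.sin(2 * np.pi * 10 * t + ph - lag)]))
    est = lfp.multitaper_spectra(np.stack(trials), tapers)
    cg = coh.imaginary_coherency(est)
    i10 = int(np.argmin(np.abs(est.freqs - 10.0)))
    self_max = float(np.abs(np.diagonal(cg.icoh, axis1=0, axis2=1)).max())
    return dict(icoh=float(cg.icoh[0, 1, i10]), target=float(np.sin(lag)),
                self_coherency_max=self_max)
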