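"""Synthetic LFP, spike, BOLD, and stereology datasets with ground truth.

The generators reproduce the statistical structure the analysis stages
assume: multi-contact LFP arrays carrying 1/f background, 60 Hz line
noise and a shared narrow-band (alpha) oscillation whose inter-areal
phase lag and per-period gain are known; Poisson spike trains with
post-injection rate steps in a configurable fraction of units; and
ROI-block-correlated BOLD runs whose amygdala-frontal correlation is
incremented post-injection under the DCZ condition.

Conventions
-----------
* ``coupling_gain`` is the in-band power ratio (SNR) of the coupled
  component to the 1/f background measured at the *bipolar-site* level;
  the raw contacts carry the oscillation with a large common-mode factor
  plus a per-contact gradient, so neighbor differencing attenuates but
  does not remove it.
* Every generator draws from a seeded generator; sub-seeds are derived
  deterministically from (seed, generator kind, condition, session), so
  a fixed config is byte-identical across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .lfp import LfpSession
from .rsfc import BoldSession, RoiAtlas
from .spikes import SpikeSession

_CONDITION_CODE = {"VEH": 0, "DCZ": 1, "CNO": 2}


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic generators."""

    seed: int = 0
    # --- LFP ---
    n_arrays: int = 2
    contacts_per_array: int = 16
    fs: float = 1000.0
    period_durations: dict = field(default_factory=lambda: dict(
        pre=600.0, waiting=900.0, post=1200.0))
    coupling_band: tuple = (9.0, 12.0)
    coupling_gain: float = 4.0          # in-band SNR at the bipolar site
    phase_lag: float = np.pi / 4
    line_noise_amp: float = 0.5
    noise_scale: float = 1.0
    common_mode_factor: float = 20.0
    # --- spikes ---
    spike_units: int = 30               # per area
    baseline_rate: float = 5.0
    rate_step: float = 2.0
    modulated_fraction: float = 0.3
    # --- BOLD ---
    bold_shape: tuple = (24, 24, 24)
    tr: float = 2.12
    n_volumes: int = 300
    n_runs: int = 3
    roi_base_corr: float = 0.1
    pair_corr: float = 0.3
    delta_r: float = 0.2
    bold_voxel_noise: float = 1.0
    # --- stereology ---
    expression_p: float = 0.05
    nissl_totals: dict = field(default_factory=lambda: {"H": 7998, "L": 10239})

    def __post_init__(self):
        lo, hi = self.coupling_band
        if not (0 < lo < hi < self.fs / 2):
            raise SynthError("coupling band must lie within (0, Nyquist)")
        if self.coupling_gain < 0:
            raise SynthError("coupling_gain must be >= 0")
        if not 0 <= self.modulated_fraction <= 1:
            raise SynthError("modulated_fraction must be in [0, 1]")
        if self.baseline_rate <= 0:
            raise SynthError("baseline_rate must be positive")
        if not 0 <= self.expression_p <= 1:
            raise SynthError("expression probability must be in [0, 1]")
        if abs(self.delta_r) >= 1 - self.pair_corr:
            raise SynthError("|delta_r| must be < 1 - baseline correlation")

    @property
    def injection_s(self) -> float:
        return float(self.period_durations["pre"])

    @property
    def duration_s(self) -> float:
        return float(sum(self.period_durations.values()))


@dataclass
class GroundTruth:
    """What the generators actually injected."""

    true_band: tuple = None             # (low, high, peak) Hz
    true_modulated_units: dict = field(default_factory=dict)  # uid -> dir
    true_delta_z: dict = field(default_factory=dict)          # pair -> dz


def _rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed)] +
                                                        [int(k) for k in keys]))


# ---------------------------------------------------------------------------
# LFP

def _noise_psd(f: np.ndarray, noise_scale: float, fs: float) -> np.ndarray:
    """One-sided 1/f PSD, flat below 0.5 Hz, total variance noise_scale^2."""
    c = noise_scale ** 2 / (1.0 + np.log(fs / 2 / 0.5))
    return c / np.maximum(f, 0.5)


def _band_envelope(f: np.ndarray, band) -> np.ndarray:
    """Hann power envelope over the coupling band (unit peak)."""
    lo, hi = band
    e = np.zeros_like(f)
    sel = (f >= lo) & (f <= hi)
    e[sel] = np.sin(np.pi * (f[sel] - lo) / (hi - lo)) ** 2
    return e


def _synth_spectrum_noise(rng, n, fs, psd):
    """Real noise with the given one-sided PSD sampled on the rfft grid."""
    amp = np.sqrt(psd * fs * n / 2.0)
    xr = rng.standard_normal(n // 2 + 1)
    xi = rng.standard_normal(n // 2 + 1)
    spec = amp * (xr + 1j * xi) / np.sqrt(2)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real * np.sqrt(2)
    return sfft.irfft(spec, n)


def _analytic_band_noise(rng, n, fs, band, psd_peak):
    """Complex analytic narrow-band noise; Re() has the band-shaped PSD.

    The PSD of the real part is ``psd_peak * Hann envelope``; the
    imaginary part is its quadrature, so multiplying by exp(-i*phi)
    applies an exact constant phase lag across the band.
    """
    f = np.fft.rfftfreq(n, 1 / fs)
    psd = psd_peak * _band_envelope(f, band)
    amp = np.sqrt(psd * fs * n / 2.0)
    xr = rng.standard_normal(len(f))
    xi = rng.standard_normal(len(f))
    half = amp * (xr + 1j * xi) / np.sqrt(2)
    full = np.zeros(n, dtype=complex)
    full[: len(f)] = 2.0 * half
    full[0] = 0.0
    if n % 2 == 0:
        full[n // 2] = 0.0
    return sfft.ifft(full)


def default_period_plan(condition: str, post_factor: float = 1.5) -> dict:
    """Coupling-SNR multipliers per period; drug raises the post gain."""
    if condition in ("DCZ", "CNO"):
        return {"pre": 1.0, "post": post_factor}
    return {"pre": 1.0, "post": 1.0}


def expected_icoh_profile(config: SynthConfig, plan: dict,
                          freqs: np.ndarray = None) -> np.ndarray:
    """Closed-form expected imaginary coherency on the analysis grid.

    Per period the inter-areal coherence at the site level is
    c(f)/(1 + c(f)) with in-band SNR c(f) = gain * plan * E(f), and the
    imaginary part is that times sin(phase lag).  Periods are averaged
    and the profile smoothed by a +/-1 Hz boxcar, emulating the taper
    bandwidth of the estimator.
    """
    if freqs is None:
        freqs = np.arange(1.0, 100.25, 0.5)
    fc = 0.5 * (config.coupling_band[0] + config.coupling_band[1])
    # coupled power is referenced to the background PSD at band center;
    # the 1/f background tilts the in-band SNR by f/fc
    env = _band_envelope(freqs, config.coupling_band) * freqs / fc
    profiles = []
    for period, mult in plan.items():
        snr = config.coupling_gain * mult * env
        profiles.append(np.sin(config.phase_lag) * snr / (1.0 + snr))
    prof = np.mean(profiles, axis=0)
    width = int(round(1.0 / (freqs[1] - freqs[0])))
    kernel = np.ones(2 * width + 1) / (2 * width + 1)
    return np.convolve(prof, kernel, mode="same")


def expected_band(config: SynthConfig, plan: dict) -> tuple:
    """Ground-truth (low, high, peak) from the expected profile (FW 1/3)."""
    freqs = np.arange(1.0, 100.25, 0.5)
    prof = np.abs(expected_icoh_profile(config, plan, freqs))
    peak = int(np.argmax(prof))
    thresh = prof[peak] / 3.0 * (1 - 1e-9)
    lo = peak
    while lo > 0 and prof[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < prof.size - 1 and prof[hi + 1] >= thresh:
        hi += 1
    return (float(freqs[lo]), float(freqs[hi]), float(freqs[peak]))


def generate_lfp_session(config: SynthConfig, condition: str = "DCZ",
                         period_plan: dict = None,
                         session_index: int = 0):
    """Continuous multi-contact LFP with known inter-areal alpha coupling.

    Each contact carries independent 1/f noise plus the shared band-
    limited oscillation (with the vlPFC array lagged by ``phase_lag``)
    and an optional common 60 Hz sinusoid.  Returns the session and its
    ground truth.
    """
    if period_plan is None:
        period_plan = default_period_plan(condition)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    rng = _rng(config.seed, 0, _CONDITION_CODE.get(condition, 9),
               session_index)
    f = np.fft.rfftfreq(n, 1 / fs)

    # shared narrow-band analytic component, site-level unit-SNR scale
    fc = 0.5 * (config.coupling_band[0] + config.coupling_band[1])
    nb_fc = 2.0 * _noise_psd(np.array([fc]), config.noise_scale, fs)[0]
    z = _analytic_band_noise(rng, n, fs, config.coupling_band, nb_fc)

    # piecewise per-period amplitude (waiting shares the post gain)
    amp = np.empty(n)
    i_inj = int(round(config.injection_s * fs))
    amp[:i_inj] = np.sqrt(period_plan.get("pre", 1.0))
    amp[i_inj:] = np.sqrt(period_plan.get("post", 1.0))

    line = config.line_noise_amp * np.sin(
        2 * np.pi * 60.0 * np.arange(n) / fs + rng.uniform(0, 2 * np.pi))

    names = ["amygdala", "vlpfc", "amygdala_contra"][: config.n_arrays]
    lags = {"amygdala": 0.0, "vlpfc": config.phase_lag,
            "amygdala_contra": 0.0}
    npsd = _noise_psd(f, config.noise_scale, fs)
    sqrt_gain = np.sqrt(config.coupling_gain)
    signal = np.empty((config.n_arrays * config.contacts_per_array, n))
    layout = {}
    row = 0
    for name in names:
        comp = np.real(z * np.exp(-1j * lags[name])) * amp
        contacts = []
        for j in range(config.contacts_per_array):
            g = sqrt_gain * (config.common_mode_factor + j)
            signal[row] = (_synth_spectrum_noise(rng, n, fs, npsd)
                           + g * comp + line)
            contacts.append(row)
            row += 1
        layout[name] = contacts

    session = LfpSession(signal=signal, fs=fs, layout=layout,
                         injection_s=config.injection_s,
                         condition=condition, subject="synthetic")
    truth = GroundTruth(true_band=expected_band(config, period_plan)
                        if config.coupling_gain > 0 else None)
    return session, truth


# ---------------------------------------------------------------------------
# spikes

def generate_spike_session(config: SynthConfig, condition: str = "DCZ",
                           session_index: int = 0):
    """Poisson spike trains; a fraction of units steps rate at injection.

    Under the vehicle condition all units are stationary; under a drug
    condition ``modulated_fraction`` of each area's units multiply their
    rate by ``rate_step`` from the injection timestamp onward.
    """
    rng = _rng(config.seed, 1, _CONDITION_CODE.get(condition, 9),
               session_index)
    duration = config.duration_s
    inj = config.injection_s
    drug = condition != "VEH"
    direction = ("increase" if config.rate_step > 1
                 else "decrease" if config.rate_step < 1 else "none")
    units, area, truth_units = {}, {}, {}
    for aname, prefix in (("amygdala", "amy"), ("vlpfc", "vl")):
        n_units = config.spike_units
        n_mod = int(round(config.modulated_fraction * n_units)) if drug else 0
        mod_ids = rng.choice(n_units, size=n_mod, replace=False)
        for u in range(n_units):
            uid = f"{prefix}{u:03d}"
            modulated = u in mod_ids and config.rate_step != 1.0
            segs = [(0.0, inj, config.baseline_rate),
                    (inj, duration, config.baseline_rate
                     * (config.rate_step if modulated else 1.0))]
            times = []
            for t0, t1, rate in segs:
                k = rng.poisson(rate * (t1 - t0))
                times.append(rng.uniform(t0, t1, size=k))
            units[uid] = np.sort(np.concatenate(times))
            area[uid] = aname
            if modulated:
                truth_units[uid] = direction
    sess = SpikeSession(units=units, area=area, injection_s=inj,
                        condition=condition, subject="synthetic")
    return sess, GroundTruth(true_modulated_units=truth_units)


# ---------------------------------------------------------------------------
# BOLD

ROI_NAMES = {1: "amygdala_l", 2: "vlpfc_l", 3: "control_l",
             4: "amygdala_r", 5: "vlpfc_r", 6: "control_r"}
_COUPLED_PAIRS = [("amygdala_l", "vlpfc_l"), ("amygdala_r", "vlpfc_r")]


def default_atlas(shape=(24, 24, 24)) -> RoiAtlas:
    """Six cuboid ROIs tiling the grid: x-halves crossed with y-thirds."""
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=int)
    for xi, xs in enumerate((slice(0, nx // 2), slice(nx // 2, nx))):
        for yi in range(3):
            ys = slice(yi * ny // 3, (yi + 1) * ny // 3)
            labels[xs, ys, :] = 3 * xi + yi + 1
    return RoiAtlas(labels=labels, names=dict(ROI_NAMES), family="custom")


def _roi_correlation(config: SynthConfig, incremented: bool) -> np.ndarray:
    names = list(ROI_NAMES.values())
    k = len(names)
    r = np.full((k, k), config.roi_base_corr)
    np.fill_diagonal(r, 1.0)
    for a, b in _COUPLED_PAIRS:
        i, j = names.index(a), names.index(b)
        val = config.pair_corr + (config.delta_r if incremented else 0.0)
        r[i, j] = r[j, i] = val
    return r


def generate_bold_session(config: SynthConfig, condition: str = "DCZ",
                          session_index: int = 0):
    """ROI-block-correlated BOLD runs; DCZ increments amygdala-vlPFC r post.

    Each run draws ROI latent series from the period's correlation
    matrix; voxel series are their ROI's latent plus i.i.d. noise.
    """
    atlas = default_atlas(config.bold_shape)
    rng = _rng(config.seed, 2, _CONDITION_CODE.get(condition, 9),
               session_index)
    names = list(ROI_NAMES.values())
    runs, periods = [], []
    for period in ("pre", "post"):
        incremented = (condition == "DCZ") and period == "post"
        r = _roi_correlation(config, incremented)
        try:
            chol = np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            raise SynthError("ROI covariance not positive-definite after "
                             "increment") from None
        roi_of_voxel = atlas.labels.reshape(-1) - 1
        for _ in range(config.n_runs):
            latent = rng.standard_normal((config.n_volumes, len(names))) @ chol.T
            vox = (latent[:, roi_of_voxel]
                   + config.bold_voxel_noise
                   * rng.standard_normal((config.n_volumes,
                                          roi_of_voxel.size)))
            runs.append(np.ascontiguousarray(
                vox.T.reshape(config.bold_shape + (config.n_volumes,))
                .astype(np.float32)))
            periods.append(period)
    session = BoldSession(runs=runs, period=periods, condition=condition,
                          subject="synthetic", tr=config.tr)
    truth = GroundTruth(true_delta_z=_true_delta_z(config, condition, atlas))
    return session, truth, atlas


def _true_delta_z(config: SynthConfig, condition: str,
                  atlas: RoiAtlas) -> dict:
    """Expected Fisher-z increment of the ROI-mean correlations.

    ROI means retain a small attenuation 1/(1 + sigma^2/V) from the
    voxel noise; included for exactness.
    """
    if condition != "DCZ":
        return {p: 0.0 for p in _COUPLED_PAIRS}
    out = {}
    for a, b in _COUPLED_PAIRS:
        va = int(np.sum(atlas.labels == [k for k, v in ROI_NAMES.items()
                                         if v == a][0]))
        vb = int(np.sum(atlas.labels == [k for k, v in ROI_NAMES.items()
                                         if v == b][0]))
        att = 1.0 / np.sqrt((1 + config.bold_voxel_noise ** 2 / va)
                            * (1 + config.bold_voxel_noise ** 2 / vb))
        r0 = config.pair_corr * att
        r1 = (config.pair_corr + config.delta_r) * att
        out[(a, b)] = float(np.arctanh(r1) - np.arctanh(r0))
    return out


# ---------------------------------------------------------------------------
# stereology

def generate_cell_counts(config: SynthConfig) -> pd.DataFrame:
    """Binomial DAB-positive counts given per-animal Nissl totals."""
    rng = _rng(config.seed, 3)
    rows = []
    for animal, nissl in config.nissl_totals.items():
        dab = int(rng.binomial(int(nissl), config.expression_p))
        rows.append(dict(animal=animal, dab_positive=dab,
                         nissl_positive=int(nissl)))
    return pd.DataFrame(rows)
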