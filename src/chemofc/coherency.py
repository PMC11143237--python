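"""Imaginary coherency between amygdala and vlPFC bipolar sites.

The imaginary part of the coherency is insensitive to zero-lag
(volume-conducted) coupling, so any non-zero value reflects phase-lagged
interaction between sites.  Cross-spectra pool 50 trials x 7 tapers per
repetition; a matched permutation null is built by independently
re-assigning each site's trials, destroying cross-site association
while preserving everything else.  Significance uses signed-rank tests
of observed vs null per frequency bin with the p < 0.01 x 5-consecutive-
bins rule, and a band of interest is read off the grand-average profile
as the full width at one third of the peak maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

from .anova import two_way_anova
from .lfp import (BipolarSignal, PeriodDefinition, SpectralEstimate,
                  TaperSet, consecutive_significance, dpss_tapers,
                  repetition_slot_indices, slot_fourier)

logger = logging.getLogger(__name__)


class CoherencyError(ValueError):
    pass


@dataclass
class Coherogram:
    """Site x site x frequency imaginary coherency (repetition-averaged)."""

    icoh: np.ndarray
    freqs: np.ndarray
    period: str = ""
    condition: str = ""
    is_null: bool = False
    site_arrays: np.ndarray = None  # array label per site


@dataclass
class BandOfInterest:
    """Coherency peak and its full width at one third of the maximum."""

    low_hz: float
    high_hz: float
    peak_hz: float
    subject: str = ""

    def __post_init__(self):
        if not self.low_hz <= self.peak_hz <= self.high_hz:
            raise CoherencyError("band bounds must bracket the peak")


def _cross_spectra(x: np.ndarray) -> np.ndarray:
    """(n_obs, n_sites, n_freq) complex -> (n_sites, n_sites, n_freq)."""
    m = np.ascontiguousarray(np.moveaxis(x, -1, 0))  # (F, obs, sites)
    s = np.matmul(m.transpose(0, 2, 1), m.conj()) / x.shape[0]
    return np.moveaxis(s, 0, -1)


def _icoh_from_cross(s: np.ndarray) -> np.ndarray:
    """(sites, sites, freq) cross-spectra -> imaginary coherency."""
    power = np.real(np.einsum("ssf->sf", s))
    if np.any(power <= 0):
        site, bin_ = np.argwhere(power <= 0)[0]
        raise CoherencyError(f"zero power at site {site}, bin {bin_}")
    denom = np.sqrt(power[:, None, :] * power[None, :, :])
    return np.imag(s) / denom


def imaginary_coherency(spectra: SpectralEstimate,
                        site_arrays=None) -> Coherogram:
    """Im( S_xy / sqrt(S_xx S_yy) ) per site pair and frequency bin.

    S is averaged over trials and tapers (degrees of freedom pooled);
    averaging over repetitions is the caller's responsibility.
    """
    x = spectra.fourier
    ntr, ntap, nsite, nfq = x.shape
    s = _cross_spectra(x.reshape(ntr * ntap, nsite, nfq))
    icoh = _icoh_from_cross(s)
    return Coherogram(icoh=icoh, freqs=spectra.freqs,
                      site_arrays=None if site_arrays is None
                      else np.asarray(site_arrays))


def scramble_site_trials(fourier: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Independently permute the trial axis for every site."""
    out = np.empty_like(fourier)
    for s in range(fourier.shape[2]):
        out[:, :, s, :] = fourier[rng.permutation(fourier.shape[0]), :, s, :]
    return out


def null_coherogram(spectra: SpectralEstimate, seed: int,
                    site_arrays=None) -> Coherogram:
    """Matched permutation null: trial assignment scrambled per site."""
    rng = np.random.default_rng(seed)
    null = scramble_site_trials(spectra.fourier, rng)
    cg = imaginary_coherency(
        SpectralEstimate(fourier=null, freqs=spectra.freqs, fs=spectra.fs),
        site_arrays=site_arrays)
    cg.is_null = True
    return cg


# ---------------------------------------------------------------------------
# session driver (slot-cached, repetition-averaged)

@dataclass
class SessionCoherency:
    """Repetition-averaged observed and null coherograms per period."""

    observed: dict      # period -> Coherogram
    null: dict          # period -> Coherogram
    freqs: np.ndarray
    site_arrays: np.ndarray


def session_coherency(bipolar: BipolarSignal, periods: PeriodDefinition,
                      n_repetitions: int = 100, n_trials: int = 50,
                      seed: int = 0, tapers: TaperSet = None,
                      filtered: np.ndarray = None,
                      which=("pre", "post")) -> SessionCoherency:
    """Full per-session coherency estimation with matched nulls.

    Each repetition draws ``n_trials`` 4-s slots, pools trials x tapers
    into cross-spectra, and the imaginary coherency is averaged across
    repetitions.  Per-slot Fourier coefficients are computed once per
    period and indexed by each repetition, which is numerically identical
    to transforming every repetition separately.
    """
    data = bipolar.accepted() if filtered is None else filtered
    arrays = bipolar.array_of()
    if tapers is None:
        tapers = dpss_tapers(n_samples=4000, fs=bipolar.fs)
    observed, null = {}, {}
    for pi, period in enumerate(which):
        window = periods.window(period)
        coeffs = slot_fourier(data, bipolar.fs, window, tapers)
        coeffs = coeffs.astype(np.complex64)
        n_slots, ntap, nsite, nfq = coeffs.shape
        freqs = np.arange(1.0, 100.0 + 0.25, 0.5)[:nfq]
        rng_null = np.random.default_rng(
            np.random.SeedSequence([int(seed), 1000 + pi]))
        sels = np.stack([
            repetition_slot_indices(n_slots, n_trials, rep, seed + 7919 * pi)
            for rep in range(n_repetitions)])
        acc_obs = np.zeros((nsite, nsite, nfq))
        acc_null = np.zeros_like(acc_obs)
        # chunk repetitions to bound memory of the batched cross-spectra
        chunk = max(1, int(2e8 // (n_trials * ntap * nsite * nfq * 8)))
        for r0 in range(0, n_repetitions, chunk):
            sel = sels[r0:r0 + chunk]
            x4 = coeffs[sel]                 # (R, trials, tapers, sites, F)
            r = x4.shape[0]
            perms = rng_null.permuted(
                np.broadcast_to(np.arange(n_trials),
                                (r, nsite, n_trials)).copy(), axis=-1)
            idx = perms.transpose(0, 2, 1)[:, :, None, :, None]
            x4n = np.take_along_axis(x4, idx, axis=1)
            for x in (x4, x4n):
                obs = x.reshape(r, n_trials * ntap, nsite, nfq)
                m = np.ascontiguousarray(obs.transpose(0, 3, 1, 2))
                s = np.matmul(m.transpose(0, 1, 3, 2), m.conj())
                s = np.moveaxis(s, 1, -1) / obs.shape[1]   # (R, S, S, F)
                power = np.real(np.einsum("rssf->rsf", s))
                if np.any(power <= 0):
                    raise CoherencyError("zero power at a site/bin")
                denom = np.sqrt(power[:, :, None, :] * power[:, None, :, :])
                icoh = (np.imag(s) / denom).sum(axis=0)
                if x is x4:
                    acc_obs += icoh
                else:
                    acc_null += icoh
        observed[period] = Coherogram(icoh=acc_obs / n_repetitions,
                                      freqs=freqs, period=period,
                                      site_arrays=arrays)
        null[period] = Coherogram(icoh=acc_null / n_repetitions, freqs=freqs,
                                  period=period, is_null=True,
                                  site_arrays=arrays)
    freqs = observed[which[0]].freqs
    return SessionCoherency(observed=observed, null=null, freqs=freqs,
                            site_arrays=arrays)


def inter_areal_pairs(site_arrays, amy_label="amygdala", vlpfc_label="vlpfc"):
    """Index pairs (amygdala site, vlPFC site); contralateral sites whose
    array label is neither are ignored."""
    site_arrays = np.asarray(site_arrays)
    amy = np.where(np.char.startswith(site_arrays.astype(str), amy_label))[0]
    vl = np.where(np.char.startswith(site_arrays.astype(str), vlpfc_label))[0]
    return amy, vl


def pair_values(icoh: np.ndarray, amy_idx, vlpfc_idx) -> np.ndarray:
    """icoh values for every amygdala x vlPFC pair, (n_pairs, n_freq)."""
    return icoh[np.ix_(amy_idx, vlpfc_idx)].reshape(-1, icoh.shape[-1])


def coherency_significance(observed, null, amy_idx, vlpfc_idx,
                           alpha: float = 0.01, run_length: int = 5):
    """Per-bin signed-rank of observed vs matched-null coherency.

    ``observed``/``null`` are repetition-averaged coherograms (or lists
    thereof, e.g. per period, whose pair values are pooled).  Returns
    (p per bin, consecutive-run significance mask).
    """
    obs_list = observed if isinstance(observed, (list, tuple)) else [observed]
    null_list = null if isinstance(null, (list, tuple)) else [null]
    dv = np.concatenate([
        pair_values(o.icoh, amy_idx, vlpfc_idx)
        - pair_values(n.icoh, amy_idx, vlpfc_idx)
        for o, n in zip(obs_list, null_list)], axis=0)
    if dv.shape[0] < 6:
        raise CoherencyError("fewer than 6 amygdala-vlPFC pairs; unpowered")
    p = np.empty(dv.shape[1])
    for j in range(dv.shape[1]):
        col = dv[:, j]
        if np.all(col == 0):
            p[j] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p[j] = wilcoxon(col, zero_method="wilcox",
                            alternative="two-sided").pvalue
    return p, consecutive_significance(p, alpha=alpha, run_length=run_length)


# ---------------------------------------------------------------------------
# band of interest

def extract_band(profile: np.ndarray, freqs: np.ndarray, mask: np.ndarray,
                 subject: str = "") -> BandOfInterest:
    """Peak and full width at one third of the peak maximum.

    ``profile`` is the grand-average amygdala-vlPFC coherency across
    periods and conditions; the peak is the largest |value| within the
    significance mask (ties toward lower frequency) and the band is the
    contiguous interval around it where |value| stays >= peak/3.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise CoherencyError("no significant coherency; band undefined")
    m = np.abs(np.asarray(profile, dtype=float))
    inmask = np.where(mask, m, -np.inf)
    peak = int(np.argmax(inmask))          # first max -> lower-frequency tie
    # relative tolerance so exact one-third crossings land inside the band
    thresh = m[peak] / 3.0 * (1 - 1e-9)
    lo = peak
    while lo > 0 and m[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < m.size - 1 and m[hi + 1] >= thresh:
        hi += 1
    return BandOfInterest(low_hz=float(freqs[lo]), high_hz=float(freqs[hi]),
                          peak_hz=float(freqs[peak]), subject=subject)


def combine_bands(bands) -> BandOfInterest:
    """Cross-subject band: min of lows to max of highs.

    A single band is returned unchanged.  For several, the combined peak
    is the grid-rounded mean of the subject peaks (reporting only; the
    band edges are what downstream averaging uses).
    """
    bands = list(bands)
    if not bands:
        raise CoherencyError("no bands to combine")
    if len(bands) == 1:
        b = bands[0]
        return BandOfInterest(b.low_hz, b.high_hz, b.peak_hz, subject="combined")
    low = min(b.low_hz for b in bands)
    high = max(b.high_hz for b in bands)
    for a in bands:
        for b in bands:
            if a.high_hz < b.low_hz:
                warnings.warn("combined band spans non-overlapping subject "
                              "bands")
                break
    peak = float(np.clip(round(np.mean([b.peak_hz for b in bands]) * 2) / 2,
                         low, high))
    return BandOfInterest(low_hz=low, high_hz=high, peak_hz=peak,
                          subject="combined")


def band_mean(icoh: np.ndarray, freqs: np.ndarray, band: BandOfInterest):
    sel = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not sel.any():
        raise CoherencyError("band outside the frequency grid")
    return icoh[..., sel].mean(axis=-1)


def band_coherency_change(coh_pre: Coherogram, coh_post: Coherogram,
                          band: BandOfInterest, amy_idx, vlpfc_idx,
                          condition: str = "", subject: str = "",
                          session: str = ""):
    """Per-amygdala-site mean band coherency with all vlPFC sites, post - pre.

    Returns a DataFrame with one row per accepted amygdala site
    (columns: pre, post, diff, condition, subject, session).
    """
    import pandas as pd

    if len(vlpfc_idx) == 0:
        raise CoherencyError("no accepted vlPFC sites")
    rows = []
    for a in amy_idx:
        pre = band_mean(coh_pre.icoh[a, vlpfc_idx, :], coh_pre.freqs,
                        band).mean()
        post = band_mean(coh_post.icoh[a, vlpfc_idx, :], coh_post.freqs,
                         band).mean()
        rows.append(dict(amy_site=int(a), pre=float(pre), post=float(post),
                         diff=float(post - pre), condition=condition,
                         subject=subject, session=session))
    return pd.DataFrame(rows)


def drug_effect_anova(diffs, response: str = "diff"):
    """Two-way type-II ANOVA of per-site coherency changes.

    Factors: drug condition and subject, plus their interaction; returns
    a table with F, df and p per term.
    """
    return two_way_anova(diffs, response=response,
                         factors=("condition", "subject"))
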