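"""Firing-rate normalization, population comparisons, and modulation flags.

Rates are binned in 30-s windows, z-scored by the pre-injection mean and
SD, and a unit counts as modulated when |z| exceeds 1.96 in at least
4 post-injection bins (10 % of a 20-min post period; the bins need not
be consecutive).  Population-level drug effects use signed-rank and
Kruskal-Wallis tests, and the proportion of modulated units is modeled
with a mixed-effects logistic regression (random animal intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, wilcoxon

from .anova import mixed_logistic
from .lfp import PeriodDefinition

logger = logging.getLogger(__name__)

BIN_S = 30.0
Z_THRESHOLD = 1.96
MIN_BINS = 4


class SpikeError(ValueError):
    pass


class SilentUnitError(SpikeError):
    """Pre-injection SD is zero; the unit cannot be normalized."""


@dataclass
class SpikeSession:
    """Sorted spike times per unit with area labels and injection metadata."""

    units: dict          # unit id -> np.ndarray of spike times (s), sorted
    area: dict           # unit id -> {"amygdala", "vlpfc"}
    injection_s: float
    condition: str
    subject: str = ""

    def __post_init__(self):
        for uid, t in self.units.items():
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) < 0):
                raise SpikeError(f"unit {uid}: spike times not sorted")
            if uid not in self.area:
                raise SpikeError(f"unit {uid}: missing area label")
            self.units[uid] = t


@dataclass
class FiringRateSeries:
    """30-s binned rates with pre-normalized z values."""

    rate_pre: np.ndarray
    rate_post: np.ndarray
    z_pre: np.ndarray
    z_post: np.ndarray
    bin_s: float = BIN_S


@dataclass
class ModulationResult:
    modulated: bool
    direction: str              # "increase" | "decrease" | "none"
    n_super_threshold_bins: int


def _bin_counts(times: np.ndarray, window: tuple, bin_s: float) -> np.ndarray:
    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_s))
    edges = t0 + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(times, bins=edges)
    return counts


def bin_rates(times: np.ndarray, periods: PeriodDefinition,
              bin_s: float = BIN_S) -> FiringRateSeries:
    """Bin a unit's spikes into 30-s windows and z-score by the pre period.

    A 10-min pre period gives 20 bins and a 20-min post period 40 bins.
    Raises :class:`SilentUnitError` when the pre-period SD is zero (the
    caller excludes such units and logs them).
    """
    times = np.asarray(times, dtype=float)
    rate_pre = _bin_counts(times, periods.pre, bin_s) / bin_s
    rate_post = _bin_counts(times, periods.post, bin_s) / bin_s
    mu = rate_pre.mean()
    sd = rate_pre.std()          # population (n) denominator
    if sd == 0:
        raise SilentUnitError("zero pre-injection SD (silent or constant unit)")
    return FiringRateSeries(rate_pre=rate_pre, rate_post=rate_post,
                            z_pre=(rate_pre - mu) / sd,
                            z_post=(rate_post - mu) / sd, bin_s=bin_s)


def period_change(series: FiringRateSeries) -> float:
    """Mean post-injection z minus mean pre-injection z for one unit."""
    return float(series.z_post.mean() - series.z_pre.mean())


def detect_modulation(series: FiringRateSeries,
                      threshold: float = Z_THRESHOLD,
                      min_bins: int = MIN_BINS,
                      consecutive: bool = False) -> ModulationResult:
    """Flag a unit whose |z| exceeds the threshold in >= ``min_bins`` bins.

    Bins are not required to be adjacent by default (``consecutive=True``
    enforces a single run).  Direction is the majority sign of the
    super-threshold bins; an exact tie gives "none".
    """
    z = series.z_post
    over = np.abs(z) > threshold
    if consecutive:
        best = run = 0
        for o in over:
            run = run + 1 if o else 0
            best = max(best, run)
        n_over = best
    else:
        n_over = int(over.sum())
    modulated = n_over >= min_bins
    direction = "none"
    if modulated:
        signs = np.sign(z[over])
        s = signs.sum()
        direction = "increase" if s > 0 else "decrease" if s < 0 else "none"
    return ModulationResult(modulated=modulated, direction=direction,
                            n_super_threshold_bins=int(over.sum()))


def session_unit_table(session: SpikeSession, periods: PeriodDefinition,
                       bin_s: float = BIN_S) -> pd.DataFrame:
    """Per-unit rate change and modulation verdicts for one session.

    Silent units (zero pre SD) are excluded with a log entry.
    """
    rows = []
    for uid, times in session.units.items():
        try:
            series = bin_rates(times, periods, bin_s=bin_s)
        except SilentUnitError:
            logger.info("unit %s excluded: zero pre-injection SD", uid)
            continue
        mod = detect_modulation(series)
        rows.append(dict(unit=uid, area=session.area[uid],
                         condition=session.condition, subject=session.subject,
                         diff=period_change(series),
                         modulated=mod.modulated, direction=mod.direction,
                         n_super_threshold_bins=mod.n_super_threshold_bins))
    return pd.DataFrame(rows)


def population_tests(table: pd.DataFrame) -> dict:
    """Population firing-rate statistics.

    Signed-rank of per-unit (post - pre) changes against zero within each
    area x condition group, and Kruskal-Wallis between drug conditions
    within each area.  Requires >= 6 units per group.
    """
    out = {"signed_rank": {}, "kruskal": {}}
    for (area, cond), g in table.groupby(["area", "condition"]):
        if len(g) == 0:
            raise SpikeError(f"empty group {area}/{cond}")
        if len(g) < 6:
            raise SpikeError(f"group {area}/{cond} has < 6 units")
        d = g["diff"].to_numpy()
        p = 1.0 if np.all(d == 0) else float(
            wilcoxon(d, zero_method="wilcox", alternative="two-sided").pvalue)
        out["signed_rank"][(area, cond)] = p
    for area, g in table.groupby("area"):
        conds = sorted(g["condition"].unique())
        if len(conds) < 2:
            continue
        groups = [g.loc[g["condition"] == c, "diff"].to_numpy() for c in conds]
        if np.ptp(np.concatenate(groups)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = kruskal(*groups)
        out["kruskal"][area] = {"chi2": float(stat),
                                "df": len(conds) - 1, "p": float(p)}
    return out


def modulation_proportion_model(table: pd.DataFrame) -> pd.DataFrame:
    """Mixed-effects logistic model of the modulated-unit proportion.

    Fixed effects: area, drug condition and their interaction; random
    intercept per animal.  Returns one row per term with the estimate,
    a T/z statistic and its p value; a separated design triggers a
    penalized fixed-effects fallback flagged in ``attrs['separated']``.
    """
    if table["condition"].nunique() < 2:
        raise SpikeError("both condition levels must be present")
    df = table.copy()
    df["modulated"] = df["modulated"].astype(int)
    return mixed_logistic(df, response="modulated",
                          fixed="C(area) * C(condition)", group="subject")
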