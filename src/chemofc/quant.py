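"""Stereological expression quantification and pipeline orchestration."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class QuantError(ValueError):
    pass


@dataclass
class CellCounts:
    """Optical-fractionator counts for one animal (DAB vs Nissl probes)."""

    animal: str
    dab_positive: int
    nissl_positive: int
    sections: int = 5

    def __post_init__(self):
        if self.dab_positive < 0 or self.nissl_positive < 0:
            raise QuantError("counts must be non-negative")


def expression_fraction(counts) -> float:
    """Percent DREADD-expressing cells: 100 * DAB-positive / Nissl-positive.

    Reported rounded to two decimals (round-half-even); accepts a
    :class:`CellCounts` or a ``(dab, nissl)`` pair.
    """
    if isinstance(counts, CellCounts):
        dab, nissl = counts.dab_positive, counts.nissl_positive
    else:
        dab, nissl = counts
    if nissl == 0:
        raise QuantError("Nissl-positive count is zero")
    return round(100.0 * dab / nissl, 2)


def expression_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-animal expression percentages from a cell-count table."""
    out = df.copy()
    out["fraction_raw"] = 100.0 * out["dab_positive"] / out["nissl_positive"]
    out["fraction_pct"] = [expression_fraction((d, n)) for d, n in
                           zip(out["dab_positive"], out["nissl_positive"])]
    return out


# ---------------------------------------------------------------------------
# pipeline

DEFAULT_STAGES = ("simulate", "lfp", "coherency", "spikes", "quantify")


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute the requested stages on one synthetic session pair.

    ``config`` keys: ``seed``, ``stages``, ``synth`` (SynthConfig
    overrides), ``analysis`` (n_repetitions, n_trials, band).  Writes a
    manifest (versions, seeds, parameters), per-stage CSV/JSON outputs,
    and returns the summary dict.  Reruns with the same config are
    numerically identical.
    """
    from . import __version__
    from .coherency import (band_coherency_change, coherency_significance,
                            extract_band, inter_areal_pairs,
                            session_coherency)
    from .lfp import (PeriodDefinition, apply_filters, bipolar_reference,
                      reject_sites)
    from .spikes import population_tests, session_unit_table
    from .synth import (SynthConfig, generate_cell_counts,
                        generate_lfp_session, generate_spike_session)

    stages = tuple(config.get("stages", DEFAULT_STAGES))
    band_spec = config.get("analysis", {}).get("band", "auto")
    if band_spec != "auto":
        try:
            lo, hi = (float(x) for x in str(band_spec).split(":"))
        except Exception:
            raise QuantError(f"invalid band {band_spec!r}; use 'auto' or "
                             "'LOW:HIGH'") from None
        if lo >= hi:
            raise QuantError("band low must be below band high")

    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    synth_cfg = SynthConfig(seed=seed, **config.get("synth", {}))
    analysis = config.get("analysis", {})
    n_reps = int(analysis.get("n_repetitions", 20))
    n_trials = int(analysis.get("n_trials", 50))
    summary: dict = {}
    manifest = dict(version=__version__, seed=seed, stages=list(stages),
                    synth=config.get("synth", {}), analysis=analysis)

    needs_lfp = any(s in stages for s in ("lfp", "coherency"))
    if needs_lfp and "simulate" not in stages:
        raise QuantError("stage 'lfp'/'coherency' requires producer stage "
                         "'simulate'")
    if "spikes" in stages and "simulate" not in stages:
        raise QuantError("stage 'spikes' requires producer stage 'simulate'")

    sessions = {}
    if "simulate" in stages:
        for cond in ("VEH", "DCZ"):
            lfp_sess, lfp_truth = generate_lfp_session(synth_cfg, cond)
            spk_sess, spk_truth = generate_spike_session(synth_cfg, cond)
            sessions[cond] = dict(lfp=lfp_sess, spikes=spk_sess,
                                  truth=dict(band=lfp_truth.true_band,
                                             units=list(
                                                 spk_truth.true_modulated_units)))
        summary["simulate"] = {c: s["truth"] for c, s in sessions.items()}

    if needs_lfp:
        periods = {}
        band_profiles = []
        per_cond = {}
        for cond, s in sessions.items():
            sess = s["lfp"]
            per = PeriodDefinition.from_injection(
                sess.injection_s, cond,
                pre_s=synth_cfg.period_durations["pre"],
                post_s=synth_cfg.period_durations["post"],
                waiting_s=synth_cfg.period_durations["waiting"])
            periods[cond] = per
            bip = reject_sites(bipolar_reference(sess))
            filt = apply_filters(bip.accepted(), sess.fs)
            res = session_coherency(bip, per, n_repetitions=n_reps,
                                    n_trials=n_trials, seed=seed,
                                    filtered=filt)
            per_cond[cond] = res
        if "coherency" in stages:
            amy, vl = inter_areal_pairs(per_cond["DCZ"].site_arrays)
            obs = [r.observed[p] for r in per_cond.values()
                   for p in ("pre", "post")]
            nul = [r.null[p] for r in per_cond.values()
                   for p in ("pre", "post")]
            p, mask = coherency_significance(obs, nul, amy, vl)
            if band_spec == "auto":
                prof = np.mean([o.icoh[np.ix_(amy, vl)].mean(axis=(0, 1))
                                for o in obs], axis=0)
                band = extract_band(prof, per_cond["DCZ"].freqs, mask)
            else:
                from .coherency import BandOfInterest
                band = BandOfInterest(lo, hi, (lo + hi) / 2, subject="config")
            tables = []
            for cond, r in per_cond.items():
                tables.append(band_coherency_change(
                    r.observed["pre"], r.observed["post"], band, amy, vl,
                    condition=cond, subject="synthetic"))
            tab = pd.concat(tables, ignore_index=True)
            tab.to_csv(os.path.join(outdir, "band_coherency.csv"),
                       index=False)
            summary["coherency"] = dict(
                band=dict(low_hz=band.low_hz, high_hz=band.high_hz,
                          peak_hz=band.peak_hz),
                mean_diff_by_condition={
                    c: float(g["diff"].mean())
                    for c, g in tab.groupby("condition")})

    if "spikes" in stages:
        tabs = []
        for cond, s in sessions.items():
            per = PeriodDefinition.from_injection(
                s["spikes"].injection_s, cond,
                pre_s=synth_cfg.period_durations["pre"],
                post_s=synth_cfg.period_durations["post"],
                waiting_s=synth_cfg.period_durations["waiting"])
            tabs.append(session_unit_table(s["spikes"], per))
        spk = pd.concat(tabs, ignore_index=True)
        spk.to_csv(os.path.join(outdir, "units.csv"), index=False)
        pop = population_tests(spk)
        summary["spikes"] = dict(
            modulated_fraction={c: float(g["modulated"].mean())
                                for c, g in spk.groupby("condition")},
            signed_rank={f"{a}/{c}": p for (a, c), p
                         in pop["signed_rank"].items()},
            kruskal=pop["kruskal"])

    if "quantify" in stages:
        counts = generate_cell_counts(synth_cfg)
        table = expression_table(counts)
        table.to_csv(os.path.join(outdir, "cell_counts.csv"), index=False)
        summary["quantify"] = dict(zip(table["animal"],
                                       table["fraction_pct"]))

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
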