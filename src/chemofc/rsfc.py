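"""Resting-state fMRI functional connectivity with drug-vs-vehicle logic.

Seed maps are Fisher-z transformed Pearson correlations between the
seed-mean series and every voxel; the drug effect is the difference of
differences [drug(post - pre)] - [vehicle(post - pre)].  Statistical
maps are BH-FDR corrected, split by sign, and cluster-thresholded with
face (6-neighbor) adjacency and a 30-voxel minimum extent.  ROI x ROI
connectomes and voxel-pair amygdala-vlPFC analyses follow the same
difference-of-differences arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .anova import fisher_z, two_way_anova

logger = logging.getLogger(__name__)

P_CLUSTER_FORMING = 0.0485
MIN_CLUSTER_VOXELS = 30


class RsfcError(ValueError):
    pass


@dataclass
class BoldSession:
    """Preprocessed 4D runs grouped into pre/post-injection periods."""

    runs: list            # list of (x, y, z, t) arrays
    period: list          # "pre" | "post" per run
    condition: str
    subject: str = ""
    brain_mask: np.ndarray = None
    tr: float = 2.12
    preprocessed: bool = True

    def __post_init__(self):
        shapes = {r.shape[:3] for r in self.runs}
        if len(shapes) != 1:
            raise RsfcError("all runs must share one voxel grid")
        if self.brain_mask is None:
            self.brain_mask = np.ones(next(iter(shapes)), dtype=bool)
        if self.brain_mask.shape != next(iter(shapes)):
            raise RsfcError("mask grid differs from the runs")

    def period_runs(self, period: str) -> list:
        return [r for r, p in zip(self.runs, self.period) if p == period]


@dataclass
class RoiAtlas:
    """Integer-labeled parcellation; label 0 is background."""

    labels: np.ndarray
    names: dict                 # label -> name
    family: str = "custom"

    def __post_init__(self):
        present = set(np.unique(self.labels)) - {0}
        missing = set(self.names) - present
        if missing:
            raise RsfcError(f"atlas labels missing from volume: {missing}")


@dataclass
class SeedMap:
    z: np.ndarray
    n_timepoints: int
    seed_label: str = ""
    period: str = ""
    condition: str = ""
    n_constant_voxels: int = 0


@dataclass
class DiffMap:
    z_diff: np.ndarray
    n_timepoints: int
    provenance: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    labels: np.ndarray          # cluster id per voxel (0 = none)
    table: pd.DataFrame         # id, size, sign, peak
    p_thresh: float = P_CLUSTER_FORMING
    min_size: int = MIN_CLUSTER_VOXELS


@dataclass
class Connectome:
    z: np.ndarray               # ROI x ROI Fisher z, diagonal NaN
    roi_labels: list
    n_timepoints: int
    family: str = "custom"
    period: str = ""
    condition: str = ""


# ---------------------------------------------------------------------------
# time-series assembly

def period_timeseries(session: BoldSession, period: str) -> np.ndarray:
    """Concatenate a period's runs after per-run standardization.

    Each voxel series is demeaned and variance-normalized within each
    run before concatenation; returns (x, y, z, T_total).
    """
    runs = session.period_runs(period)
    if not runs:
        raise RsfcError(f"no runs for period {period!r}")
    std_runs = []
    for r in runs:
        r = np.asarray(r, dtype=float)
        mu = r.mean(axis=-1, keepdims=True)
        sd = r.std(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            std_runs.append(np.where(sd > 0, (r - mu) / sd, 0.0))
    return np.concatenate(std_runs, axis=-1)


def _corr_with(series: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of every voxel series (…, T) with a reference (T,)."""
    ref = (ref - ref.mean()) / ref.std()
    x = series - series.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ ref) / (series.shape[-1] * sd)
    return np.where(sd > 0, r, np.nan)


# ---------------------------------------------------------------------------
# seed maps and difference-of-differences

def seed_map(session: BoldSession, seed_mask: np.ndarray, period: str,
             seed_label: str = "amygdala") -> SeedMap:
    """Fisher-z map of correlation with the seed-mean time series."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not (seed_mask & session.brain_mask).any():
        raise RsfcError("seed mask empty within the brain mask")
    data = period_timeseries(session, period)
    seed_ts = data[seed_mask & session.brain_mask].mean(axis=0)
    r = _corr_with(data, seed_ts)
    n_const = int(np.isnan(r[session.brain_mask]).sum())
    if n_const:
        logger.warning("seed_map: %d constant voxel series set to z = 0",
                       n_const)
    z = np.where(np.isnan(r), 0.0, fisher_z(np.nan_to_num(r)))
    z[~session.brain_mask] = 0.0
    return SeedMap(z=z, n_timepoints=data.shape[-1], seed_label=seed_label,
                   period=period, condition=session.condition,
                   n_constant_voxels=n_const)


def difference_of_differences(cond_post, cond_pre, veh_post, veh_pre) -> DiffMap:
    """[drug(post - pre)] - [vehicle(post - pre)], voxelwise.

    Inputs are :class:`SeedMap` objects or plain z arrays on one grid
    (session-averaged inputs are supported).
    """
    def _z(m):
        return m.z if isinstance(m, SeedMap) else np.asarray(m, dtype=float)

    arrs = [_z(m) for m in (cond_post, cond_pre, veh_post, veh_pre)]
    if len({a.shape for a in arrs}) != 1:
        raise RsfcError("grid mismatch between input maps")
    nt = min((m.n_timepoints for m in (cond_post, cond_pre, veh_post, veh_pre)
              if isinstance(m, SeedMap)), default=0)
    return DiffMap(z_diff=(arrs[0] - arrs[1]) - (arrs[2] - arrs[3]),
                   n_timepoints=nt,
                   provenance={"order": ["cond_post", "cond_pre",
                                         "veh_post", "veh_pre"]})


# ---------------------------------------------------------------------------
# thresholding and clusterization

def diffmap_p_values(diffmap: DiffMap, n_timepoints: int = None) -> np.ndarray:
    """Two-sided normal p for a difference of four Fisher-z maps.

    Each z has variance ~ 1/(n - 3) with n in-period timepoints, so the
    difference of differences has variance 4/(n - 3).
    """
    n = n_timepoints or diffmap.n_timepoints
    if n <= 3:
        raise RsfcError("need more than 3 timepoints for Fisher variance")
    sigma = np.sqrt(4.0 / (n - 3))
    return 2 * norm.sf(np.abs(diffmap.z_diff) / sigma)


def threshold_and_clusterize(diffmap: DiffMap, n_timepoints: int = None,
                             q: float = 0.05,
                             p_thresh: float = P_CLUSTER_FORMING,
                             min_size: int = MIN_CLUSTER_VOXELS,
                             mask: np.ndarray = None) -> ClusterResult:
    """BH-FDR at ``q``, sign-split face-adjacency clustering, extent filter.

    Positive and negative voxels are clustered separately with
    6-connectivity ("at least one side in contact"); components smaller
    than ``min_size`` voxels are dropped.  An empty surviving set is a
    valid (empty) result.
    """
    p = diffmap_p_values(diffmap, n_timepoints)
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    flat_p = p[mask]
    reject = np.zeros(p.shape, dtype=bool)
    if flat_p.size:
        reject[mask] = multipletests(flat_p, alpha=q, method="fdr_bh")[0]
    surviving = reject & (p <= p_thresh)
    structure = ndimage.generate_binary_structure(3, 1)   # faces only
    labels = np.zeros(p.shape, dtype=int)
    rows = []
    next_id = 1
    for sign, sel in ((1, surviving & (diffmap.z_diff > 0)),
                      (-1, surviving & (diffmap.z_diff < 0))):
        lab, n = ndimage.label(sel, structure=structure)
        for comp in range(1, n + 1):
            vox = lab == comp
            size = int(vox.sum())
            if size < min_size:
                continue
            labels[vox] = next_id
            rows.append(dict(cluster=next_id, size=size, sign=sign,
                             peak=float(np.max(np.abs(diffmap.z_diff[vox])))))
            next_id += 1
    table = pd.DataFrame(rows, columns=["cluster", "size", "sign", "peak"])
    return ClusterResult(labels=labels, table=table, p_thresh=p_thresh,
                         min_size=min_size)


# ---------------------------------------------------------------------------
# connectomes

def roi_connectome(session: BoldSession, atlas: RoiAtlas,
                   period: str) -> Connectome:
    """Fisher-z matrix of pairwise ROI-mean correlations for one period."""
    data = period_timeseries(session, period)
    series, kept = [], []
    for label in sorted(atlas.names):
        vox = (atlas.labels == label) & session.brain_mask
        if not vox.any():
            logger.info("ROI %s has no in-mask voxels; excluded",
                        atlas.names[label])
            continue
        series.append(data[vox].mean(axis=0))
        kept.append(label)
    if len(kept) < 2:
        raise RsfcError("need >= 2 ROIs with in-mask voxels")
    r = np.corrcoef(np.stack(series))
    z = fisher_z(r)
    np.fill_diagonal(z, np.nan)
    return Connectome(z=z, roi_labels=kept, n_timepoints=data.shape[-1],
                      family=atlas.family, period=period,
                      condition=session.condition)


def connectome_session_diff(session: BoldSession, atlas: RoiAtlas) -> Connectome:
    """Post-injection minus pre-injection connectome for one session."""
    pre = roi_connectome(session, atlas, "pre")
    post = roi_connectome(session, atlas, "post")
    if pre.roi_labels != post.roi_labels:
        raise RsfcError("ROI sets differ between periods")
    return Connectome(z=post.z - pre.z, roi_labels=pre.roi_labels,
                      n_timepoints=min(pre.n_timepoints, post.n_timepoints),
                      family=atlas.family, period="post-pre",
                      condition=session.condition)


def connectome_change(cond_sessions, veh_sessions, atlas: RoiAtlas):
    """Difference-of-differences connectome across sessions.

    Per-session (post - pre) matrices are averaged within each condition
    and the vehicle mean is subtracted from the drug mean.  Returns
    (diff matrix, drug mean, vehicle mean, roi labels).
    """
    def _mean(sessions):
        diffs = [connectome_session_diff(s, atlas) for s in sessions]
        labels = diffs[0].roi_labels
        if any(d.roi_labels != labels for d in diffs):
            raise RsfcError("ROI sets differ across sessions")
        return np.mean([d.z for d in diffs], axis=0), labels

    cond_mean, labels = _mean(cond_sessions)
    veh_mean, labels_v = _mean(veh_sessions)
    if labels != labels_v:
        raise RsfcError("ROI sets differ across conditions")
    return cond_mean - veh_mean, cond_mean, veh_mean, labels


def connectome_long_table(sessions, atlas: RoiAtlas) -> pd.DataFrame:
    """Per-session, per-ROI-pair (post - pre) z changes in long form."""
    rows = []
    for si, s in enumerate(sessions):
        d = connectome_session_diff(s, atlas)
        k = len(d.roi_labels)
        iu = np.triu_indices(k, 1)
        for i, j in zip(*iu):
            rows.append(dict(
                dz=float(d.z[i, j]),
                pair=f"{d.roi_labels[i]}-{d.roi_labels[j]}",
                condition=s.condition, subject=s.subject,
                session=f"{s.subject}:{si}"))
    return pd.DataFrame(rows)


def connectome_anova(table: pd.DataFrame) -> pd.DataFrame:
    """ANOVA of per-pair connectome changes: drug x subject, ROI pair block.

    The ROI pair enters as a blocking factor (the balanced-design
    equivalent of a random effect); session is nested within subject by
    construction of the long table.  A single-subject design drops the
    subject factor with a warning.
    """
    return two_way_anova(table, response="dz",
                         factors=("condition", "subject"), block="pair")


# ---------------------------------------------------------------------------
# voxel-pair amygdala-vlPFC analysis

def hemisphere_mask(shape, hemisphere: str) -> np.ndarray:
    """Left/right half of the grid split at the x midline."""
    nx = shape[0]
    m = np.zeros(shape, dtype=bool)
    if hemisphere == "left":
        m[: nx // 2] = True
    elif hemisphere == "right":
        m[nx // 2:] = True
    else:
        raise RsfcError(f"unknown hemisphere {hemisphere!r}")
    return m


def voxel_pair_map(session: BoldSession, amy_mask, vlpfc_mask,
                   period: str) -> np.ndarray:
    """Mean vlPFC Fisher-z per amygdala voxel, projected into the volume.

    For each amygdala voxel the Fisher-z correlation with every vlPFC
    voxel is averaged; voxels outside the amygdala mask are NaN.
    """
    amy_mask = np.asarray(amy_mask, dtype=bool) & session.brain_mask
    vl_mask = np.asarray(vlpfc_mask, dtype=bool) & session.brain_mask
    if not amy_mask.any() or not vl_mask.any():
        raise RsfcError("empty amygdala or vlPFC mask in this hemisphere")
    data = period_timeseries(session, period)
    a = data[amy_mask]
    v = data[vl_mask]
    a = (a - a.mean(-1, keepdims=True))
    v = (v - v.mean(-1, keepdims=True))
    asd = a.std(-1)
    vsd = v.std(-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a @ v.T) / (data.shape[-1] * np.outer(asd, vsd))
    z = fisher_z(np.nan_to_num(r))
    out = np.full(session.brain_mask.shape, np.nan)
    out[amy_mask] = z.mean(axis=1)
    return out


def voxel_pair_fc(cond_session: BoldSession, veh_session: BoldSession,
                  amy_mask, vlpfc_mask, hemisphere: str = None) -> np.ndarray:
    """Per-amygdala-voxel [drug(post - pre)] - [vehicle(post - pre)] map.

    Hemispheres are analyzed independently when ``hemisphere`` is given
    ("left"/"right"): both masks are restricted to that half.
    """
    if hemisphere is not None:
        hm = hemisphere_mask(np.asarray(amy_mask).shape, hemisphere)
        amy_mask = np.asarray(amy_mask, dtype=bool) & hm
        vlpfc_mask = np.asarray(vlpfc_mask, dtype=bool) & hm
    maps = {}
    for name, sess in (("cond", cond_session), ("veh", veh_session)):
        maps[name] = {p: voxel_pair_map(sess, amy_mask, vlpfc_mask, p)
                      for p in ("pre", "post")}
    return ((maps["cond"]["post"] - maps["cond"]["pre"])
            - (maps["veh"]["post"] - maps["veh"]["pre"]))


def global_fc_test(table: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of voxelwise z changes with drug and animal factors.

    Voxels are pooled across sessions (one row per voxel per session),
    matching the degrees of freedom of whole-brain voxel-correlation
    summaries.
    """
    return two_way_anova(table, response="dz",
                         factors=("condition", "subject"))
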