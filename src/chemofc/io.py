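"""Readers and writers for the session formats.

LFP and spikes share one HDF5 file per session
(``/lfp/array{name}/contact{j}``, ``/spikes/unit{uid}/times``; root
attrs ``fs``, ``injection_s``, ``condition``, ``subject``).  BOLD runs
are 4D NIfTI-1 with an integer NIfTI atlas and a JSON sidecar holding
TR, condition and per-run period tags.  Cell counts are plain CSV.
"""

from __future__ import annotations

import json
import os

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .lfp import LfpSession
from .rsfc import BoldSession, RoiAtlas
from .spikes import SpikeSession


def save_ephys_hdf5(path, lfp: LfpSession = None, spikes: SpikeSession = None):
    with h5py.File(path, "w") as h5:
        ref = lfp or spikes
        h5.attrs["fs"] = float(lfp.fs) if lfp is not None else 0.0
        h5.attrs["injection_s"] = float(ref.injection_s)
        h5.attrs["condition"] = ref.condition
        h5.attrs["subject"] = ref.subject
        if lfp is not None:
            g = h5.create_group("lfp")
            for name, contacts in lfp.layout.items():
                ga = g.create_group(f"array{name}")
                for j, c in enumerate(contacts):
                    ga.create_dataset(f"contact{j}", data=lfp.signal[c],
                                      compression="gzip", compression_opts=1)
        if spikes is not None:
            g = h5.create_group("spikes")
            for uid, times in spikes.units.items():
                gu = g.create_group(f"unit{uid}")
                gu.create_dataset("times", data=np.asarray(times))
                gu.attrs["area"] = spikes.area[uid]


def load_lfp_hdf5(path) -> LfpSession:
    with h5py.File(path, "r") as h5:
        g = h5["lfp"]
        layout, rows = {}, []
        for aname in sorted(g):
            contacts = []
            ga = g[aname]
            for cname in sorted(ga, key=lambda s: int(s.removeprefix("contact"))):
                contacts.append(len(rows))
                rows.append(ga[cname][()])
            layout[aname.removeprefix("array")] = contacts
        return LfpSession(signal=np.stack(rows), fs=float(h5.attrs["fs"]),
                          layout=layout,
                          injection_s=float(h5.attrs["injection_s"]),
                          condition=str(h5.attrs["condition"]),
                          subject=str(h5.attrs["subject"]))


def load_spikes_hdf5(path) -> SpikeSession:
    with h5py.File(path, "r") as h5:
        g = h5["spikes"]
        units, area = {}, {}
        for uname in sorted(g):
            uid = uname.removeprefix("unit")
            units[uid] = g[uname]["times"][()]
            area[uid] = str(g[uname].attrs["area"])
        return SpikeSession(units=units, area=area,
                            injection_s=float(h5.attrs["injection_s"]),
                            condition=str(h5.attrs["condition"]),
                            subject=str(h5.attrs["subject"]))


def save_bold(outdir, session: BoldSession, atlas: RoiAtlas = None,
              prefix: str = "bold"):
    os.makedirs(outdir, exist_ok=True)
    affine = np.eye(4)
    for i, (run, period) in enumerate(zip(session.runs, session.period)):
        img = nib.Nifti1Image(np.asarray(run, dtype=np.float32), affine)
        img.header.set_zooms((1.0, 1.0, 1.0, session.tr))
        nib.save(img, os.path.join(outdir, f"{prefix}_run{i:02d}.nii.gz"))
    if atlas is not None:
        nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine),
                 os.path.join(outdir, f"{prefix}_atlas.nii.gz"))
    sidecar = dict(tr=session.tr, condition=session.condition,
                   subject=session.subject, period=list(session.period),
                   atlas_names={int(k): v for k, v in
                                (atlas.names.items() if atlas else [])})
    with open(os.path.join(outdir, f"{prefix}_sidecar.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_bold(outdir, prefix: str = "bold"):
    with open(os.path.join(outdir, f"{prefix}_sidecar.json")) as fh:
        sidecar = json.load(fh)
    runs = []
    i = 0
    while True:
        p = os.path.join(outdir, f"{prefix}_run{i:02d}.nii.gz")
        if not os.path.exists(p):
            break
        runs.append(np.asanyarray(nib.load(p).dataobj))
        i += 1
    session = BoldSession(runs=runs, period=sidecar["period"],
                          condition=sidecar["condition"],
                          subject=sidecar.get("subject", ""),
                          tr=sidecar["tr"])
    atlas = None
    ap = os.path.join(outdir, f"{prefix}_atlas.nii.gz")
    if os.path.exists(ap):
        labels = np.asanyarray(nib.load(ap).dataobj).astype(int)
        atlas = RoiAtlas(labels=labels,
                         names={int(k): v for k, v in
                                sidecar.get("atlas_names", {}).items()})
    return session, atlas


def save_cell_counts(path, counts: pd.DataFrame):
    counts.to_csv(path, index=False)


def load_cell_counts(path) -> pd.DataFrame:
    return pd.read_csv(path)
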