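"""HDF5 persistence for recordings, epoch sets and CSTP models."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .containers import ContinuousRecording, EpochSet
from .cstp import CSTP

__all__ = [
    "save_cohort", "load_cohort", "save_epochs", "load_epochs",
    "save_cstp_model", "load_cstp_model",
]


def save_cohort(cohort, path, config=None) -> None:
    """One HDF5 group per subject: data, sfreq, channels, event table."""
    with h5py.File(path, "w") as f:
        if config is not None:
            f.attrs["config_json"] = json.dumps(config)
        for sid, group, rec in cohort:
            g = f.create_group(sid)
            g.attrs["group"] = group
            g.attrs["sfreq"] = rec.sfreq
            g.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
            g.create_dataset("channels", data=np.array(rec.channels, dtype="S"))
            g.create_dataset("event_onsets", data=np.array([o for o, _ in rec.events]))
            g.create_dataset("event_codes",
                             data=np.array([c for _, c in rec.events], dtype="S"))


def load_cohort(path):
    cohort = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            rec = ContinuousRecording(
                data=g["data"][...],
                sfreq=float(g.attrs["sfreq"]),
                channels=[c.decode() for c in g["channels"][...]],
                events=list(zip(g["event_onsets"][...].astype(int).tolist(),
                                [c.decode() for c in g["event_codes"][...]])),
            )
            cohort.append((sid, str(g.attrs["group"]), rec))
    return cohort


def save_epochs(ep: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sfreq"] = ep.sfreq
        f.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
        f.create_dataset("t_axis", data=ep.t_axis)
        f.create_dataset("channels", data=np.array(ep.channels, dtype="S"))
        meta = f.create_group("meta")
        for col in ep.meta.columns:
            vals = ep.meta[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            meta.create_dataset(col, data=vals)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = {}
        for col in f["meta"]:
            vals = f["meta"][col][...]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            meta[col] = vals
        return EpochSet(
            data=f["data"][...],
            channels=[c.decode() for c in f["channels"][...]],
            sfreq=float(f.attrs["sfreq"]),
            t_axis=f["t_axis"][...],
            meta=pd.DataFrame(meta),
        )


def save_cstp_model(model: CSTP, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["params_json"] = json.dumps(model.get_params())
        f.attrs["converged"] = bool(model.converged_)
        for name in ("W_", "V_", "sigma1_", "sigma2_", "r1_", "r2_",
                     "objective_trace_", "spatial_eigvals_"):
            f.create_dataset(name, data=getattr(model, name))
        f.create_dataset("classes_", data=np.asarray(model.classes_, dtype="S"))


def load_cstp_model(path) -> CSTP:
    with h5py.File(path, "r") as f:
        model = CSTP(**json.loads(f.attrs["params_json"]))
        for name in ("W_", "V_", "sigma1_", "sigma2_", "r1_", "r2_",
                     "objective_trace_", "spatial_eigvals_"):
            setattr(model, name, f[name][...])
        model.converged_ = bool(f.attrs["converged"])
        model.classes_ = np.array([c.decode() for c in f["classes_"][...]])
    return model
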