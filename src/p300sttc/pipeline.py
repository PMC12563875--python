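"""End-to-end reproducible pipeline: simulate -> preprocess -> CSTP ->
group statistics -> (optional) classifier cross-validation.

A single root seed deterministically derives all stage seeds; every artifact
is listed in a manifest with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .containers import TARGET
from .cstp import CSTP
from .evaluate import cross_validate_sttcnet, make_folds, raw_svm_control, svm_baseline
from .io import save_cohort, save_cstp_model, save_epochs
from .preprocess import preprocess_cohort
from .simulate import SimulationConfig, simulate_cohort
from .stats import channel_stats, topography_values

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    return {
        "seed": 0,
        "simulation": SimulationConfig().to_dict(),
        "preprocess": {"lo": 0.1, "hi": 30.0, "window_ms": [-100.0, 600.0],
                       "baseline_ms": [-100.0, 0.0], "target_sfreq": 250.0},
        "cstp": {"m_filters": 6, "k_filters": 6, "max_iter": 20, "tol": 1e-6},
        "evaluate": {"enabled": False, "k_folds": 4, "baselines": True,
                     "net": {"d_model": 32, "n_heads": 4, "ffn_dim": 64,
                             "mlp_hidden": 32, "max_epochs": 20, "patience": 10}},
    }


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def _file_hash(path: Path) -> str:
    """Content hash; HDF5 files are hashed structurally (names, attrs, data)
    so the hash does not depend on write timestamps embedded in the format."""
    if path.suffix != ".h5":
        return hashlib.sha256(path.read_bytes()).hexdigest()
    import h5py

    h = hashlib.sha256()
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            h.update(name.encode())
            for k in sorted(obj.attrs):
                h.update(k.encode())
                h.update(str(obj.attrs[k]).encode())
            if isinstance(obj, h5py.Dataset):
                h.update(np.ascontiguousarray(obj[...]).tobytes())
        f.visititems(visit)
    return h.hexdigest()


def _require(cfg: dict, key: str) -> dict:
    if key not in cfg:
        raise ValueError(f"missing required config field: {key!r}")
    return cfg[key]


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run every stage, write artifacts under ``outdir``, return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg.get("seed", 0))
    artifacts: list[Path] = []

    def _save(path: Path):
        artifacts.append(path)
        return path

    # -- simulate -------------------------------------------------------------
    sim_cfg = SimulationConfig.from_dict(_require(cfg, "simulation"))
    sim_cfg.seed = _stage_seed(root_seed, "simulate")
    logger.info("simulating cohort (%d per group)", sim_cfg.n_subjects_per_group)
    cohort = simulate_cohort(sim_cfg)
    save_cohort(cohort, _save(out / "cohort.h5"), config=sim_cfg.to_dict())

    # -- preprocess -----------------------------------------------------------
    pp = _require(cfg, "preprocess")
    ep = preprocess_cohort(
        cohort, lo=pp["lo"], hi=pp["hi"], window_ms=tuple(pp["window_ms"]),
        baseline_ms=tuple(pp["baseline_ms"]), target_sfreq=pp["target_sfreq"])
    save_epochs(ep, _save(out / "epochs.h5"))
    targets = ep.select_code(TARGET)

    # -- CSTP -----------------------------------------------------------------
    cc = _require(cfg, "cstp")
    cstp = CSTP(**cc).fit(targets.data, targets.meta["group"].to_numpy())
    save_cstp_model(cstp, _save(out / "cstp_model.h5"))
    feats = cstp.transform(targets.data)
    feat_df = targets.meta.copy()
    for j in range(feats.shape[1]):
        kind = "space" if j < cstp.m_filters else "time"
        feat_df[f"f_{kind}_{j if j < cstp.m_filters else j - cstp.m_filters}"] = feats[:, j]
    feat_df.to_csv(_save(out / "cstp_features.csv"), index=False)

    # -- group statistics -----------------------------------------------------
    channel_stats(targets).to_csv(_save(out / "channel_stats.csv"), index=False)
    topography_values(targets).to_csv(_save(out / "topography.csv"), index=False)

    # -- classification -------------------------------------------------------
    ev = cfg.get("evaluate", {"enabled": False})
    if ev.get("enabled", False):
        subjects = list(dict.fromkeys(targets.meta["subject_id"]))
        groups = [targets.meta.loc[targets.meta["subject_id"] == s, "group"].iloc[0]
                  for s in subjects]
        folds = make_folds(subjects, groups, k=ev.get("k_folds", 4),
                           seed=_stage_seed(root_seed, "folds"))
        report = cross_validate_sttcnet(
            targets, folds, seed=_stage_seed(root_seed, "net"), **ev.get("net", {}))
        report.to_json(_save(out / "cv_report.json"))
        if ev.get("baselines", True):
            svm_baseline(targets, folds, seed=_stage_seed(root_seed, "svm")) \
                .to_json(_save(out / "cv_svm_baseline.json"))
            raw_svm_control(targets, folds, seed=_stage_seed(root_seed, "raw")) \
                .to_json(_save(out / "cv_raw_control.json"))

    # -- manifest -------------------------------------------------------------
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "seed": root_seed,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "artifacts": {p.name: _file_hash(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
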