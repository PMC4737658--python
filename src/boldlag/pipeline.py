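"""Configurable end-to-end pipeline: simulate -> preprocess -> TD -> maps
-> threads -> stats.

The configuration is a plain mapping (typically parsed from YAML); every
stochastic stage derives its stream from the single top-level seed, so a
rerun with the same config and seed reproduces all outputs bit for bit.
"""

from __future__ import annotations

import numpy as np

from . import groupstats, lagmaps, preprocess, synthdata, threads
from .lagcore import build_td_matrix, zero_lag_fc
from .storage import config_hash

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "simulate": {
        "lattice_shape": [6, 6, 3],
        "n_subjects_per_state": 6,
        "epochs_per_subject": 1,
        "frames_per_epoch": 150,
        "noise_sd": 0.2,
    },
    "preprocess": {
        "cutoff_hz": 0.1,
        "censor_threshold_pct": 0.5,
        "min_run": 10,
        "include_global": False,
    },
    "td": {"max_lag_frames": 4, "normalize": True},
    "threads": {"k_max": 10},
    "stats": {"n_perm": 500, "alpha": 0.05, "z_threshold": 4.5},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None, seed: int = 0) -> dict:
    """Run the full synthetic-study pipeline; returns a results mapping.

    Unknown top-level stages or parameters raise before execution.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    for stage, params in cfg.items():
        if stage not in DEFAULT_CONFIG:
            raise ValueError(f"unknown pipeline stage: {stage!r}")
        unknown = set(params) - set(DEFAULT_CONFIG[stage])
        if unknown:
            raise ValueError(f"unknown parameters for {stage!r}: {sorted(unknown)}")

    sim = cfg["simulate"]
    from .lattice import LatticeGeometry

    geometry = LatticeGeometry(shape=tuple(sim["lattice_shape"]))
    design = synthdata.reorganized_two_state_design(
        geometry=geometry,
        n_subjects_per_state=sim["n_subjects_per_state"],
        epochs_per_subject=sim["epochs_per_subject"],
        frames_per_epoch=sim["frames_per_epoch"],
        noise_sd=sim["noise_sd"],
        seed=seed,
    )
    epochs = synthdata.generate_study(design)

    pp = cfg["preprocess"]
    processed, censored_pct = [], []
    for ep in epochs:
        out = preprocess.preprocess_epoch(
            ep,
            cutoff_hz=pp["cutoff_hz"],
            include_global=pp["include_global"],
            censor_threshold_pct=pp["censor_threshold_pct"],
            min_run=pp["min_run"],
        )
        censored_pct.append(100.0 * (1 - out.n_valid / out.n_frames))
        if out.has_valid_frames:
            processed.append(out)

    if not processed:
        return {
            "config_hash": config_hash(cfg),
            "seed": seed,
            "n_epochs": 0,
            "empty": True,
            "censored_pct": censored_pct,
        }

    tdp = cfg["td"]
    tds, fcs, projections = [], [], []
    subjects, states = [], []
    for ep in processed:
        td = build_td_matrix(
            ep, max_lag_frames=tdp["max_lag_frames"], normalize=tdp["normalize"]
        )
        tds.append(td)
        fcs.append(zero_lag_fc(ep))
        projections.append(lagmaps.lag_projection(td).values)
        subjects.append(ep.subject_id)
        states.append(ep.state_label)

    group_td = lagmaps.group_average(
        [np.where(td.validity, td.td, np.nan) for td in tds], subjects, states
    )
    group_proj = lagmaps.group_average(projections, subjects, states)

    st = cfg["stats"]
    sd = groupstats.lag_sd_contrast(
        tds, subjects, states, n_perm=st["n_perm"], seed=seed + 1
    )
    maps = np.stack(projections)
    cluster = groupstats.cluster_permutation_test(
        maps, subjects, states, geometry=geometry,
        z_threshold=st["z_threshold"], alpha=st["alpha"],
        n_perm=st["n_perm"], seed=seed + 2,
    )
    thread_decomp = {
        state: threads.lag_threads(
            _group_td_matrix(group_td[state]), k_max=cfg["threads"]["k_max"]
        )
        for state in group_td
    }
    return {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "empty": False,
        "n_epochs": len(processed),
        "censored_pct": censored_pct,
        "subjects": subjects,
        "states": states,
        "tds": tds,
        "fcs": fcs,
        "projections": maps,
        "group_projection": group_proj,
        "lag_sd": sd,
        "cluster": cluster,
        "threads": thread_decomp,
        "partition": design.partition,
        "geometry": geometry,
    }


def _group_td_matrix(avg: np.ndarray):
    from .lagcore import TimeDelayMatrix

    valid = np.isfinite(avg)
    td = np.where(valid, avg, 0.0)
    return TimeDelayMatrix(td=td, amp=np.zeros_like(td), validity=valid, tr=0.0)
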