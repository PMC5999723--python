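"""Plain-text interfaces: per-trial CSVs, manifests, features, config files.

The same trial-CSV layout (columns ``t_s, y_m, v_mps, a_mps2, f_load_N,
f_grip_N``) is accepted for real recordings, so the preprocessing and
statistics layers never depend on the generator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import FieldParams
from .simulate import ControllerParams, TrialMeta, TrialSeries

TRIAL_COLUMNS = ["t_s", "y_m", "v_mps", "a_mps2", "f_load_N", "f_grip_N"]

MANIFEST_COLUMNS = [
    "participant", "block", "trial", "condition", "k_Npm", "y0_cm",
    "expected_k_Npm", "expected_y0_cm", "w_m", "is_catch", "regime",
    "vp_target_mps", "truth_lag_ms", "t_impact_true_s", "file",
]


def trial_filename(meta: TrialMeta) -> str:
    return f"p{meta.participant:02d}_b{meta.block:02d}_t{meta.trial:02d}.csv"


def write_trial_csv(series: TrialSeries, path) -> None:
    df = pd.DataFrame({
        "t_s": series.t, "y_m": series.y, "v_mps": series.v,
        "a_mps2": series.a, "f_load_N": series.f_load, "f_grip_N": series.f_grip,
    })
    df.to_csv(path, index=False, float_format="%.9g")


def read_trial_csv(path, meta: TrialMeta) -> TrialSeries:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV {path} lacks columns {missing}")
    return TrialSeries(
        t=df["t_s"].to_numpy(), y=df["y_m"].to_numpy(), v=df["v_mps"].to_numpy(),
        a=df["a_mps2"].to_numpy(), f_load=df["f_load_N"].to_numpy(),
        f_grip=df["f_grip_N"].to_numpy(), meta=meta,
    )


def manifest_row(series: TrialSeries) -> dict:
    m, fp = series.meta, series.meta.field
    return {
        "participant": m.participant, "block": m.block, "trial": m.trial,
        "condition": m.condition, "k_Npm": fp.k, "y0_cm": fp.y0_cm,
        "expected_k_Npm": fp.expected_k, "expected_y0_cm": fp.expected_y0 * 100.0,
        "w_m": fp.w, "is_catch": fp.is_catch, "regime": m.regime,
        "vp_target_mps": m.vp_target, "truth_lag_ms": m.truth_lag_ms,
        "t_impact_true_s": m.t_impact_true, "file": trial_filename(m),
    }


def write_manifest(rows, path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False,
                                                        float_format="%.9g")


def meta_from_manifest_row(row) -> TrialMeta:
    is_catch = bool(row["is_catch"])
    fp = FieldParams(
        k=0.0 if is_catch else float(row["k_Npm"]),
        y0=0.0 if is_catch else float(row["y0_cm"]) / 100.0,
        w=float(row["w_m"]), is_catch=is_catch,
        expected_k=float(row["expected_k_Npm"]),
        expected_y0=float(row["expected_y0_cm"]) / 100.0,
    )
    return TrialMeta(
        participant=int(row["participant"]), block=int(row["block"]),
        trial=int(row["trial"]), condition=str(row["condition"]), field=fp,
        regime=str(row.get("regime", "")), vp_target=float(row["vp_target_mps"]),
        truth_lag_ms=float(row["truth_lag_ms"]),
        t_impact_true=float(row["t_impact_true_s"]),
    )


def read_trials(directory) -> list:
    """Load every trial listed in a directory's ``manifest.csv``."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        meta = meta_from_manifest_row(row)
        out.append(read_trial_csv(directory / row["file"], meta))
    return out


def controller_to_dict(cp: ControllerParams) -> dict:
    d = dataclasses.asdict(cp)
    for key in ("ascent_shape", "descent_shape", "vp_bounds"):
        d[key] = list(d[key])
    return d


def controller_from_dict(d: dict) -> ControllerParams:
    d = dict(d)
    for key in ("ascent_shape", "descent_shape", "vp_bounds"):
        if key in d:
            d[key] = tuple(d[key])
    return ControllerParams(**d)


def save_config(config_dict: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.bool_):
            return bool(obj)
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return super().default(obj)


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
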