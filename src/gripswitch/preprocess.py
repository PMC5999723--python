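"""Preprocessing chain from raw trial recordings to per-trial scalar features.

Mirrors the study's offline processing: velocity, acceleration and grip-force
rate are obtained by central differences and smoothed with a zero-phase
(forward-backward) 4th-order low-pass recursive filter at 20 Hz; movement
onset is the first sample from which velocity exceeds 3 cm/s for at least
100 ms; the (expected) impact is the argmax of the rendered — or, on catch
trials, reconstructed — elastic force; and per-trial scalars (peak times,
lags, grip-force rate at expected force onset, ...) feed the switching
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as _dc_fields

import numpy as np

from .design import elastic_force, mini_block_of, mini_blocks  # noqa: F401 (re-export)
from .filters import central_difference, zero_phase_lowpass
from .simulate import TrialSeries

__all__ = [
    "OnsetNotFoundError",
    "ImpactNotFoundError",
    "TrialFeatures",
    "central_difference",
    "zero_phase_lowpass",
    "derive_and_filter",
    "movement_onset",
    "impact_time",
    "extract_features",
    "features_table",
    "catch_neighbor_diffs",
    "mini_blocks",
]


class OnsetNotFoundError(RuntimeError):
    """Velocity never exceeded the onset threshold for the required duration."""


class ImpactNotFoundError(RuntimeError):
    """The trial's position never entered the (expected) elastic field."""


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(np.asarray(t, dtype=float))
    if dt.size == 0 or np.any(np.abs(dt - dt[0]) > 1e-9):
        raise ValueError("time base must be uniformly sampled")
    return 1.0 / dt[0]


def derive_and_filter(series: TrialSeries, cutoff: float = 20.0):
    """Smoothed velocity, acceleration and grip-force rate of one trial.

    Each derived channel is the central difference of the raw signal chain
    (position -> velocity -> acceleration; grip force -> grip-force rate)
    smoothed once with the zero-phase low-pass.  Outputs match the input
    length.
    """
    fs = _check_uniform(series.t)
    v_raw = central_difference(series.y, fs)
    v = zero_phase_lowpass(v_raw, fs, cutoff)
    a = zero_phase_lowpass(central_difference(v_raw, fs), fs, cutoff)
    gfr = zero_phase_lowpass(central_difference(series.f_grip, fs), fs, cutoff)
    return v, a, gfr


def movement_onset(v: np.ndarray, fs: float, threshold: float = 0.03,
                   hold: float = 0.1) -> int:
    """Index of movement onset: earliest sample from which ``v > threshold``
    holds continuously for at least ``hold`` seconds."""
    v = np.asarray(v, dtype=float)
    n_hold = max(1, int(round(hold * fs)))
    above = v > threshold
    if n_hold > above.size:
        raise OnsetNotFoundError("trial shorter than the onset hold window")
    run = np.convolve(above.astype(int), np.ones(n_hold, dtype=int), "valid")
    hits = np.nonzero(run == n_hold)[0]
    if hits.size == 0:
        raise OnsetNotFoundError(
            f"velocity never exceeded {threshold} m/s for {hold} s"
        )
    return int(hits[0])


def impact_time(series: TrialSeries):
    """(Expected) impact: time and value of the elastic-force maximum.

    Real trials use the recorded elastic load force; catch trials apply the
    scheduled field law to the recorded position.  Ties break to the
    earliest sample.  Returns ``(index, time_s, force_N)``.
    """
    fp = series.meta.field
    if fp.is_catch:
        f = elastic_force(series.y, fp.expected_field())
    else:
        f = np.asarray(series.f_load, dtype=float)
    if not np.any(f > 0):
        raise ImpactNotFoundError("position never entered the (expected) field")
    i = int(np.argmax(f))  # argmax returns the first of ties
    return i, float(series.t[i]), float(f[i])


def _first_local_max(x: np.ndarray, lo: int, hi: int, half: int = 2):
    """First strict local maximum of ``x`` on ``[lo, hi]`` over a
    ``2*half + 1``-sample neighbourhood; None if there is none."""
    n = len(x)
    for i in range(max(lo, half), min(hi, n - half - 1) + 1):
        seg = x[i - half:i + half + 1]
        if x[i] == seg.max() and np.count_nonzero(seg == x[i]) == 1:
            return i
    return None


def _refine_peak(x: np.ndarray, i: int, half: int) -> int:
    """Nearest-sample vertex of a quadratic fitted around a peak index."""
    lo, hi = max(0, i - half), min(len(x), i + half + 1)
    idx = np.arange(lo, hi)
    if idx.size < 5:
        return i
    c = np.polyfit(idx - i, x[lo:hi], 2)
    if c[0] >= 0:  # not concave: keep the raw argmax
        return i
    vertex = -c[1] / (2.0 * c[0])
    if abs(vertex) > half:
        return i
    return int(round(i + vertex))


@dataclass(frozen=True)
class TrialFeatures:
    """Scalar features of one preprocessed trial.

    Times are in seconds on the trial clock; lags in ms (positive = grip
    peak after impact).  Fields that cannot be measured on a given trial
    (e.g. a missing first local grip peak) are NaN, never fabricated.
    """

    participant: int
    block: int
    trial: int
    condition: str
    is_catch: bool
    mini_block: int
    k_Npm: float              # scheduled (expected) stiffness
    ln_k: float
    t_onset: float            # movement onset, s
    t_impact: float           # (expected) elastic-force peak time, s
    lf_peak: float            # (expected) elastic-force maximum, N
    gf_peak: float            # global grip-force maximum after onset, N
    t_gf_peak: float
    gf_first_peak: float      # first local grip maximum near first accel peak, N
    t_gf_first_peak: float
    acc_first_peak: float     # first acceleration peak after onset, m/s^2
    t_acc_first_peak: float
    vp: float                 # peak velocity between onset and impact, m/s
    lag_impact: float         # t_gf_peak - t_impact, ms
    lag_inertial: float       # t_gf_first_peak - t_acc_first_peak, ms
    gfr_at_onset: float       # grip-force rate at expected force onset, N/s
    acc_at_field_onset: float  # acceleration when y first crosses y0, m/s^2


def extract_features(series: TrialSeries, cutoff: float = 20.0,
                     first_peak_window_ms: float = 150.0) -> TrialFeatures:
    """Run the full preprocessing chain on one trial.

    Raises :class:`OnsetNotFoundError` / :class:`ImpactNotFoundError` when
    the trial has no movement or never reaches the (expected) field.
    """
    fs = _check_uniform(series.t)
    v, a, gfr = derive_and_filter(series, cutoff)
    i_on = movement_onset(v, fs)
    i_imp, t_imp, lf_peak = impact_time(series)

    m = series.meta
    fp = m.field
    gf = np.asarray(series.f_grip, dtype=float)

    # global grip peak from onset onward
    i_gf = i_on + int(np.argmax(gf[i_on:]))

    # first acceleration peak: located over the early reach (the first 60%
    # of the onset-to-impact interval, before the impact region) on a
    # heavily re-smoothed copy — the peak top is flat, so the raw noisy
    # argmax scatters tens of ms — then refined by a local quadratic fit
    i_hi = i_on + max(1, int(0.6 * (i_imp - i_on))) if i_imp > i_on else i_on + 1
    a_loc = zero_phase_lowpass(a, fs, cutoff=8.0)
    i_apk = i_on + int(np.argmax(a_loc[i_on:i_hi + 1]))
    i_apk = _refine_peak(a_loc, i_apk, half=int(round(0.05 * fs)))

    # first local grip maximum within +-150 ms of the first accel peak
    half_w = int(round(first_peak_window_ms / 1000.0 * fs))
    i_gf1 = _first_local_max(gf, i_apk - half_w, i_apk + half_w)

    # expected force onset: first crossing of the scheduled y0
    y0 = fp.expected_y0
    crossings = np.nonzero(series.y >= y0)[0]
    i_cross = int(crossings[0]) if crossings.size else None

    t = series.t
    vp = float(np.max(v[i_on:i_imp + 1])) if i_imp > i_on else float(v[i_on])
    feat = TrialFeatures(
        participant=m.participant, block=m.block, trial=m.trial,
        condition=m.condition, is_catch=fp.is_catch,
        mini_block=mini_block_of(m.trial) if 1 <= m.trial <= 45 else 0,
        k_Npm=fp.expected_k, ln_k=fp.ln_k_expected,
        t_onset=float(t[i_on]), t_impact=t_imp, lf_peak=lf_peak,
        gf_peak=float(gf[i_gf]), t_gf_peak=float(t[i_gf]),
        gf_first_peak=float(gf[i_gf1]) if i_gf1 is not None else math.nan,
        t_gf_first_peak=float(t[i_gf1]) if i_gf1 is not None else math.nan,
        acc_first_peak=float(a[i_apk]), t_acc_first_peak=float(t[i_apk]),
        vp=vp,
        lag_impact=(float(t[i_gf]) - t_imp) * 1000.0,
        lag_inertial=((float(t[i_gf1]) - float(t[i_apk])) * 1000.0
                      if i_gf1 is not None else math.nan),
        gfr_at_onset=float(gfr[i_cross]) if i_cross is not None else math.nan,
        acc_at_field_onset=float(a[i_cross]) if i_cross is not None else math.nan,
    )
    return feat


def features_table(trials, cutoff: float = 20.0, on_error: str = "raise"):
    """Extract features for a collection of trials into a DataFrame.

    ``on_error="skip"`` drops trials whose onset or impact cannot be found
    (they are counted in the ``attrs['n_failed']`` of the result).
    """
    import pandas as pd

    rows, failed = [], 0
    for s in trials:
        try:
            rows.append(extract_features(s, cutoff))
        except (OnsetNotFoundError, ImpactNotFoundError):
            if on_error == "raise":
                raise
            failed += 1
    df = pd.DataFrame([{f.name: getattr(r, f.name) for f in _dc_fields(TrialFeatures)}
                       for r in rows])
    df.attrs["n_failed"] = failed
    return df


def catch_neighbor_diffs(block_features) -> "pd.DataFrame":
    """Per-catch differences of grip-force rate at expected force onset.

    For every catch trial C_t of a block, returns ``C_t - R_{t-1}`` and
    ``C_t - R_{t+1}`` where R are the immediately neighbouring real trials
    (NaN when the neighbour does not exist or is itself a catch trial).
    """
    import pandas as pd

    df = block_features.sort_values("trial").reset_index(drop=True)
    out = []
    for i, row in df.iterrows():
        if not row["is_catch"]:
            continue
        prev_diff = next_diff = math.nan
        if i > 0 and not df.loc[i - 1, "is_catch"]:
            prev_diff = row["gfr_at_onset"] - df.loc[i - 1, "gfr_at_onset"]
        if i < len(df) - 1 and not df.loc[i + 1, "is_catch"]:
            next_diff = row["gfr_at_onset"] - df.loc[i + 1, "gfr_at_onset"]
        out.append({
            "participant": row["participant"], "block": row["block"],
            "trial": row["trial"], "mini_block": row["mini_block"],
            "diff_prev": prev_diff, "diff_next": next_diff,
        })
    return pd.DataFrame(out)
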