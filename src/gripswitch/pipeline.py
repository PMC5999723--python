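"""End-to-end orchestration: simulate -> preprocess -> switching statistics.

``run_all`` executes the full synthetic experiment (default: 18 participants,
10 blocks of 45 trials each) one participant at a time, extracts per-trial
features and force-onset-aligned acceleration snippets, runs the cohort
analysis, and writes every table plus a human-readable summary to the output
directory.  ``make_fixtures`` builds the small deterministic bundles used for
exact-recovery and pathological-input tests.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gsio
from .design import FieldParams, make_schedule
from .preprocess import (
    ImpactNotFoundError,
    OnsetNotFoundError,
    derive_and_filter,
    features_table,
)
from .simulate import (
    ControllerParams,
    TrialMeta,
    TrialSeries,
    iter_cohort,
    simulate_participant,
    trial_regimes,
)
from .stats import (
    BootstrapCI,
    acc_sign_threshold,
    bootstrap_diff,
    divergence_time,
    fit_extremum,
    piecewise_fit,
    threshold_correlation,
)

__all__ = [
    "RunConfig",
    "SwitchResult",
    "aligned_accel_snippets",
    "analyze_cohort",
    "run_all",
    "make_fixtures",
    "figure_tables",
]

log = logging.getLogger("gripswitch")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    Defaults reproduce the study conditions; the resampling seed default is
    fixed for reproducibility.
    """

    n_participants: int = 18
    order: str = "counterbalanced"   # asc-first | desc-first | counterbalanced
    n_blocks: int = 10
    fs: float = 500.0
    controller: ControllerParams = field(default_factory=ControllerParams)
    cutoff_hz: float = 20.0
    bootstrap_reps: int = 10_000
    seed: int = 20180607
    accel_window_ms: float = 400.0
    outdir: str = "results"
    write_trials: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.order not in ("asc-first", "desc-first", "counterbalanced"):
            raise ValueError(f"unknown order {self.order!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["controller"] = gsio.controller_to_dict(self.controller)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "controller" in d and isinstance(d["controller"], dict):
            d["controller"] = gsio.controller_from_dict(d["controller"])
        return cls(**d)


# ---------------------------------------------------------------------------
# aligned acceleration snippets


def aligned_accel_snippets(trials, window_ms: float = 400.0,
                           cutoff: float = 20.0) -> dict:
    """Force-onset-aligned filtered acceleration rows, grouped for the
    divergence test.

    Returns ``{(participant, stiffness_group): {"real": ndarray, "catch":
    ndarray}}`` where each matrix row is one trial's filtered acceleration
    from the first crossing of the (expected) force-onset position
    ``y0 - w`` over the next ``window_ms`` ms.  The stiffness group (1 =
    softest .. 7 = stiffest) is the trial's mini-block in ascending blocks
    and its mirror ``8 - mini_block`` in descending blocks, so both
    conditions pool at matched stiffness.  Trials that never cross, or
    whose recording ends inside the window, are skipped.
    """
    from .design import mini_block_of

    store: dict = {}
    for s in trials:
        fs = s.fs
        n_win = int(round(window_ms / 1000.0 * fs))
        _, a, _ = derive_and_filter(s, cutoff)
        fp = s.meta.field
        onset_pos = fp.expected_y0 - fp.w
        crossings = np.nonzero(s.y >= onset_pos)[0]
        if crossings.size == 0:
            continue
        i0 = int(crossings[0])
        if i0 + n_win > len(a):
            continue
        mb = mini_block_of(s.meta.trial)
        group = mb if s.meta.condition == "ascending" else 8 - mb
        key = (s.meta.participant, group)
        kind = "catch" if fp.is_catch else "real"
        store.setdefault(key, {"real": [], "catch": []})[kind].append(a[i0:i0 + n_win])
    return {
        key: {kind: np.array(rows) for kind, rows in d.items()}
        for key, d in store.items()
    }


# ---------------------------------------------------------------------------
# cohort analysis


@dataclass(frozen=True)
class SwitchResult:
    """Cohort-level switching estimates plus the per-participant table."""

    per_participant: pd.DataFrame
    x_star_asc: float          # cohort extremum, ascending, ln(N/m)
    x_star_desc: float
    threshold_Npm: float       # mean of the two extrema converted to N/m
    lag_soft_ms: float         # mean lag at the softest level (real + catch)
    lag_stiff_ms: float        # mean lag at the stiffest level (real trials)
    s_lo: float                # cohort hinge slope below breakpoint, ms/ln-unit
    s_hi: float
    aic_piecewise_asc: float
    aic_linear_asc: float
    aic_piecewise_desc: float
    aic_linear_desc: float
    hysteresis_ci: BootstrapCI
    slope_ci: BootstrapCI
    divergence_ms: float       # across-mini-block mean divergence time
    divergence_by_mini_block: dict
    acc_sign_lnk: float        # cohort acceleration-sign threshold
    corr_r: float
    corr_p: float

    def report(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
             if f.name != "per_participant"}
        d["hysteresis_ci"] = dataclasses.asdict(self.hysteresis_ci)
        d["slope_ci"] = dataclasses.asdict(self.slope_ci)
        d["divergence_by_mini_block"] = {
            str(k): v for k, v in self.divergence_by_mini_block.items()
        }
        return d

    def summary(self) -> str:
        lines = [
            "Switching analysis summary",
            "--------------------------",
            f"participants:             {len(self.per_participant)}",
            f"grip-peak extremum (asc): ln k = {self.x_star_asc:.3f}"
            f"  ({math.exp(self.x_star_asc):.1f} N/m)",
            f"grip-peak extremum (desc): ln k = {self.x_star_desc:.3f}"
            f"  ({math.exp(self.x_star_desc):.1f} N/m)",
            f"switch threshold:         {self.threshold_Npm:.1f} N/m",
            f"lag, softest field:       {self.lag_soft_ms:.1f} ms",
            f"lag, stiffest field:      {self.lag_stiff_ms:.1f} ms",
            f"hinge slopes:             {self.s_lo:.1f} (below) / "
            f"{self.s_hi:.1f} (above) ms per ln-unit",
            f"hysteresis CI (asc-desc): [{self.hysteresis_ci.lo:.3f}, "
            f"{self.hysteresis_ci.hi:.3f}]"
            f"{' excludes 0' if self.hysteresis_ci.excludes_zero else ''}",
            f"slope-difference CI:      [{self.slope_ci.lo:.1f}, "
            f"{self.slope_ci.hi:.1f}]"
            f"{' excludes 0' if self.slope_ci.excludes_zero else ''}",
            f"AIC piecewise vs linear:  asc {self.aic_piecewise_asc:.1f} vs "
            f"{self.aic_linear_asc:.1f}; desc {self.aic_piecewise_desc:.1f} vs "
            f"{self.aic_linear_desc:.1f}",
            f"real/catch divergence:    {self.divergence_ms:.1f} ms after force onset",
            f"acc-sign threshold:       ln k = {self.acc_sign_lnk:.3f}",
            f"threshold correlation:    r = {self.corr_r:.3f}, p = {self.corr_p:.3f}",
        ]
        return "\n".join(lines)


def _level_means(df: pd.DataFrame, value: str, by=("ln_k",)) -> pd.DataFrame:
    return (df.dropna(subset=[value]).groupby(list(by), as_index=False)[value]
            .mean())


def analyze_cohort(features: pd.DataFrame, accel_snippets: dict, fs: float,
                   reps: int = 10_000, seed=None) -> SwitchResult:
    """Run every switching statistic on a cohort's feature table.

    ``accel_snippets`` is the output of :func:`aligned_accel_snippets`.
    Participant-level quantities (extrema, hinge slopes, acceleration-sign
    thresholds) are estimated on per-participant means per stiffness level;
    cohort fits use across-participant means.  Bootstrap CIs resample
    participants.
    """
    ss = np.random.SeedSequence(seed)
    seed_hyst, seed_slope = (int(c.generate_state(1, dtype=np.uint64)[0] >> 33)
                             for c in ss.spawn(2))

    rows = []
    for pid, pf in features.groupby("participant"):
        row = {"participant": pid}
        for cond, tag in (("ascending", "asc"), ("descending", "desc")):
            lm = _level_means(pf[pf["condition"] == cond], "gf_peak")
            fit = fit_extremum(lm["ln_k"], lm["gf_peak"], condition=cond)
            row[f"x_star_{tag}"] = fit.x_star
            row[f"r2_{tag}"] = fit.r2
        row["x_star_avg"] = 0.5 * (row["x_star_asc"] + row["x_star_desc"])
        lag_lm = _level_means(pf, "lag_impact")
        pw = piecewise_fit(lag_lm["ln_k"], lag_lm["lag_impact"], row["x_star_avg"])
        row["s_lo"], row["s_hi"] = pw.s_lo, pw.s_hi
        row["acc_sign_lnk"] = acc_sign_threshold(
            pf["ln_k"], pf["acc_at_field_onset"]) or math.nan
        rows.append(row)
    per_p = pd.DataFrame(rows).sort_values("participant").reset_index(drop=True)

    # cohort-level extrema on across-participant means per level
    cohort_x = {}
    for cond, tag in (("ascending", "asc"), ("descending", "desc")):
        sub = features[features["condition"] == cond]
        pm = _level_means(sub, "gf_peak", by=("participant", "ln_k"))
        cm = _level_means(pm, "gf_peak")
        cohort_x[tag] = fit_extremum(cm["ln_k"], cm["gf_peak"], condition=cond)
    threshold = 0.5 * (math.exp(cohort_x["asc"].x_star)
                       + math.exp(cohort_x["desc"].x_star))

    # lags at the extreme stiffness levels
    k_lo, k_hi = features["k_Npm"].min(), features["k_Npm"].max()
    soft = features[np.isclose(features["k_Npm"], k_lo)]
    stiff = features[np.isclose(features["k_Npm"], k_hi) & ~features["is_catch"]]
    lag_soft = float(soft["lag_impact"].mean())
    lag_stiff = float(stiff["lag_impact"].mean())

    # cohort hinge + per-condition AIC comparison
    xb = float(per_p["x_star_avg"].mean())
    pm_all = _level_means(features, "lag_impact", by=("participant", "ln_k"))
    cm_all = _level_means(pm_all, "lag_impact")
    pw_all = piecewise_fit(cm_all["ln_k"], cm_all["lag_impact"], xb)
    aics = {}
    for cond, tag in (("ascending", "asc"), ("descending", "desc")):
        sub = features[features["condition"] == cond]
        pm = _level_means(sub, "lag_impact", by=("participant", "ln_k"))
        cm = _level_means(pm, "lag_impact")
        pw = piecewise_fit(cm["ln_k"], cm["lag_impact"], xb)
        aics[tag] = (pw.aic_piecewise, pw.aic_linear)

    if len(per_p) >= 3:
        hyst_ci = bootstrap_diff(per_p["x_star_asc"], per_p["x_star_desc"],
                                 reps=reps, seed=seed_hyst)
        slope_ci = bootstrap_diff(per_p["s_lo"], per_p["s_hi"], reps=reps,
                                  seed=seed_slope, statistic="abs_mean_diff")
    else:  # too few participants to resample: report degenerate intervals
        hyst_ci = BootstrapCI("mean_diff",
                              float(per_p["x_star_asc"].mean()
                                    - per_p["x_star_desc"].mean()),
                              math.nan, math.nan, 0, None)
        slope_ci = BootstrapCI("abs_mean_diff",
                               float(abs(per_p["s_lo"].mean()
                                         - per_p["s_hi"].mean())),
                               math.nan, math.nan, 0, None)

    # divergence per participant x mini-block, averaged per mini-block
    by_mb: dict = {}
    for (pid, mb), mats in accel_snippets.items():
        if len(mats["real"]) < 2 or len(mats["catch"]) < 2:
            continue
        td = divergence_time(mats["real"], mats["catch"], fs)
        by_mb.setdefault(mb, []).append(td)
    div_by_mb = {mb: float(np.mean([t for t in v if t is not None]))
                 for mb, v in sorted(by_mb.items())
                 if any(t is not None for t in v)}
    div_ms = float(np.mean(list(div_by_mb.values()))) if div_by_mb else math.nan

    acc_lnk = acc_sign_threshold(features["ln_k"],
                                 features["acc_at_field_onset"])
    try:
        corr_r, corr_p = threshold_correlation(per_p["x_star_avg"],
                                               per_p["acc_sign_lnk"])
    except ValueError:
        corr_r = corr_p = math.nan

    return SwitchResult(
        per_participant=per_p,
        x_star_asc=cohort_x["asc"].x_star, x_star_desc=cohort_x["desc"].x_star,
        threshold_Npm=threshold, lag_soft_ms=lag_soft, lag_stiff_ms=lag_stiff,
        s_lo=pw_all.s_lo, s_hi=pw_all.s_hi,
        aic_piecewise_asc=aics["asc"][0], aic_linear_asc=aics["asc"][1],
        aic_piecewise_desc=aics["desc"][0], aic_linear_desc=aics["desc"][1],
        hysteresis_ci=hyst_ci, slope_ci=slope_ci,
        divergence_ms=div_ms, divergence_by_mini_block=div_by_mb,
        acc_sign_lnk=acc_lnk if acc_lnk is not None else math.nan,
        corr_r=corr_r, corr_p=corr_p,
    )


def figure_tables(features: pd.DataFrame) -> dict:
    """Plotting-ready long-format summaries of the four key relationships.

    Keys: ``gf_peak_vs_lnk`` (per condition), ``lag_vs_lnk``,
    ``inertial_lag_vs_lnk``, ``acc_at_onset_vs_lnk`` (per condition); each
    table carries mean and between-participant SEM per stiffness level.
    """
    def table(value, by_condition):
        keys = ["condition", "ln_k"] if by_condition else ["ln_k"]
        pm = (features.dropna(subset=[value])
              .groupby([*keys, "participant"], as_index=False)[value].mean())
        g = pm.groupby(keys)[value]
        out = g.mean().reset_index().rename(columns={value: "mean"})
        out["sem"] = g.sem().to_numpy()
        out["n"] = g.size().to_numpy()
        return out

    return {
        "gf_peak_vs_lnk": table("gf_peak", True),
        "lag_vs_lnk": table("lag_impact", False),
        "inertial_lag_vs_lnk": table("lag_inertial", False),
        "acc_at_onset_vs_lnk": table("acc_at_field_onset", True),
    }


# ---------------------------------------------------------------------------
# full run


def run_all(config: RunConfig) -> SwitchResult:
    """Execute the full pipeline and write the report bundle to
    ``config.outdir`` (manifest, features, per-participant and cohort
    results, figure tables, config echo, summary)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gsio.save_config(config.to_dict(), out / "config.yaml")

    cp = config.controller
    manifest_rows: list = []
    feature_frames: list = []
    snippets: dict = {}
    log.info("simulating %d participants (%d blocks each)",
             config.n_participants, config.n_blocks)
    for pid, trials in iter_cohort(config.n_participants, cp, config.order,
                                   config.n_blocks, config.fs, config.seed):
        manifest_rows.extend(gsio.manifest_row(s) for s in trials)
        if config.write_trials:
            tdir = out / "trials"
            tdir.mkdir(exist_ok=True)
            for s in trials:
                gsio.write_trial_csv(s, tdir / gsio.trial_filename(s.meta))
        try:
            feats = features_table(trials, config.cutoff_hz)
        except (OnsetNotFoundError, ImpactNotFoundError) as err:
            raise RuntimeError(
                f"feature extraction failed for participant {pid}: {err}"
            ) from err
        if feats.attrs.get("n_failed"):
            log.warning("participant %d: %d trials without usable features",
                        pid, feats.attrs["n_failed"])
        feature_frames.append(feats)
        snippets.update(aligned_accel_snippets(trials, config.accel_window_ms,
                                               config.cutoff_hz))
        log.info("participant %d/%d done", pid, config.n_participants)

    features = pd.concat(feature_frames, ignore_index=True)
    gsio.write_manifest(manifest_rows, out / "manifest.csv")
    features.to_csv(out / "features.csv", index=False, float_format="%.9g")

    log.info("running switching statistics")
    result = analyze_cohort(features, snippets, config.fs,
                            config.bootstrap_reps, config.seed)
    result.per_participant.to_csv(out / "per_participant.csv", index=False,
                                  float_format="%.9g")
    gsio.save_json(result.report(), out / "results.json")
    for name, tab in figure_tables(features).items():
        tab.to_csv(out / f"{name}.csv", index=False, float_format="%.9g")
    (out / "summary.txt").write_text(result.summary() + "\n")
    log.info("report bundle written to %s", out)
    return result


# ---------------------------------------------------------------------------
# fixtures


def _flat_trial(fp: FieldParams, fs: float = 500.0, duration: float = 2.0,
                grip: float = 2.0) -> TrialSeries:
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    zero = np.zeros(n)
    meta = TrialMeta(participant=99, block=1, trial=1, condition="ascending",
                     field=fp, regime="soft", vp_target=0.5,
                     truth_lag_ms=math.nan, t_impact_true=math.nan)
    return TrialSeries(t=t, y=zero.copy(), v=zero.copy(), a=zero.copy(),
                       f_load=zero.copy(), f_grip=np.full(n, grip), meta=meta)


def make_fixtures(seed: int = 0) -> dict:
    """Deterministic test bundles.

    * ``zero_noise`` — 2 participants x 2 blocks (one per condition) with all
      noise sources off, for exact ground-truth recovery tests;
    * ``zero_noise_controller`` — the ControllerParams used for it;
    * ``no_movement`` — flat position trace (onset must not be found);
    * ``never_enters_field`` — a small reach that stays below the field;
    * ``double_peaked_grip`` — a zero-noise trial whose grip has two separated
      local maxima near the first acceleration peak.
    """
    cp0 = ControllerParams(lag_sd=0.0, pos_noise_sd=0.0, amp_noise_frac=0.0)
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    cohort = []
    for pid, child in ((1, s1), (2, s2)):
        cohort.extend(simulate_participant(pid, cp0, order="asc-first",
                                           n_blocks=2, seed=child))

    fp_real = FieldParams(k=100.0, y0=0.05)
    no_movement = _flat_trial(fp_real)

    # a reach to 2 cm: never reaches the field boundary at 5 cm
    n = 1001
    t = np.arange(n) / 500.0
    y = 0.02 * np.sin(np.pi * np.clip(t - 0.25, 0.0, 1.0)) ** 2
    v = np.gradient(y, t)
    a = np.gradient(v, t)
    meta = TrialMeta(participant=99, block=1, trial=2, condition="ascending",
                     field=fp_real, regime="soft", vp_target=0.5,
                     truth_lag_ms=math.nan, t_impact_true=math.nan)
    never_enters = TrialSeries(t=t, y=y, v=v, a=a, f_load=np.zeros(n),
                               f_grip=np.full(n, 2.0), meta=meta)

    base = next(s for s in cohort
                if not s.meta.field.is_catch and s.meta.trial == 1
                and s.meta.participant == 1)
    # first acceleration peak of the ascent (before the position maximum)
    i_apk = int(np.argmax(base.a[:int(np.argmax(base.y))]))
    gf = base.f_grip.copy()
    for off in (-25, 25):  # two bumps 50 ms apart around the accel peak
        centre = base.t[i_apk] + off / 1000.0
        gf = gf + 0.5 * np.exp(-((base.t - centre) ** 2) / (2 * 0.01**2))
    double_peaked = TrialSeries(t=base.t, y=base.y, v=base.v, a=base.a,
                                f_load=base.f_load, f_grip=gf, meta=base.meta)

    return {
        "zero_noise": cohort,
        "zero_noise_controller": cp0,
        "no_movement": no_movement,
        "never_enters_field": never_enters,
        "double_peaked_grip": double_peaked,
    }
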