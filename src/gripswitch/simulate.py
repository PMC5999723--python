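"""Synthetic trial generator for the switched grip-force control experiment.

One simulated trial is a vertical reach of ~15.5 cm through a one-sided
elastic field, recorded at 500 Hz.  The generative model has three layers:

* **Planned kinematics** — a smooth bell-shaped velocity profile
  ``v(t) ∝ t^p (T-t)^q`` for the ascent and its min-jerk special case
  ``(p, q) = (2, 2)`` for the descent.  The ascent is skewed
  (default ``p = 3.95``) so the planned acceleration changes sign at the
  onset position of the ~147 N/m field, where the behavioural switch sits.
* **Field-perturbed dynamics** — on real trials the realized acceleration is
  the planned acceleration minus the rendered field force divided by the
  effective moving mass (no within-movement feedback correction); catch
  trials execute the plan exactly and therefore overshoot the target.
* **Grip force** — a baseline, an inertial component proportional to the
  positive part of planned acceleration (first local peak at the first
  acceleration peak), and an anticipatory Gaussian bump centred at the
  (expected) impact time plus a stiffness-dependent lag.  The lag follows a
  rise-then-plateau function of ln(stiffness) whose plateau regime engages a
  few trials after the block's stiffness schedule crosses a hysteretic
  threshold (ln k = 5.07 ascending, 4.89 descending); the bump amplitude is
  an inverted U in ln(stiffness) centred on the same threshold.

All randomness flows from a single :class:`numpy.random.SeedSequence`, so a
cohort is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.special import beta as _beta_fn
from scipy.special import betainc as _betainc

from .design import (
    BlockSchedule,
    FieldParams,
    InvalidParameterError,
    elastic_force,
    make_schedule,
)
from .filters import zero_phase_lowpass

__all__ = [
    "ControllerParams",
    "TrialMeta",
    "TrialSeries",
    "bell_profile",
    "min_jerk_duration",
    "peak_velocity_factor",
    "lag_model",
    "trial_regimes",
    "simulate_kinematics",
    "grip_profile",
    "simulate_trial",
    "simulate_participant",
    "simulate_cohort",
]

#: Internal simulation rate, Hz (device control loop); recordings are
#: decimated to the 500 Hz acquisition rate.
FS_SIM = 1000.0
LN_K_MIN = math.log(4.0 / 0.12)  # softest scheduled stiffness, ln(N/m)


@dataclass(frozen=True)
class ControllerParams:
    """Generative parameters of the simulated participant and apparatus.

    Thresholds and lags parameterize the switched feedforward controller;
    the remaining fields describe the plant (mass, planned trajectory) and
    measurement (position noise).  Defaults reproduce the study conditions.
    """

    theta_asc: float = 5.07      # switch threshold on ln k, ascending blocks
    theta_desc: float = 4.89     # switch threshold on ln k, descending blocks
    lag_soft: float = 4.0        # grip-peak lag at the softest field, ms
    lag_plateau: float = 40.0    # grip-peak lag above threshold, ms
    lag_sd: float = 6.0          # trial-to-trial lag noise SD, ms
    amp_peak: float = 10.0       # anticipatory grip amplitude at threshold, N
    amp_width: float = 1.5       # width of the amplitude curve on the ln k axis
    amp_noise_frac: float = 0.05  # multiplicative amplitude noise SD
    inertial_gain: float = 0.25  # grip N per m/s^2 of anticipated acceleration
    grip_lp_hz: float = 20.0     # muscular low-pass bandwidth of the grip drive
    gf_baseline: float = 2.0     # resting grip force, N
    bump_sd_ms: float = 80.0     # SD of the anticipatory Gaussian bump, ms
    m_eff: float = 1.2           # effective handle + arm mass, kg
    fb_stiffness: float = 22.0   # corrective-servo stiffness / mass, 1/s^2 (~0.75 Hz)
    fb_damping: float = 9.4      # corrective-servo damping / mass, 1/s (critical)
    switch_inertia_trials: int = 3  # trials after crossing before the lag regime flips
    plan_amplitude: float = 0.15    # planned movement amplitude, m (touch the target)
    ascent_shape: tuple = (3.5, 2.0)    # (p, q) of the ascent velocity bell
    descent_shape: tuple = (2.0, 2.0)   # min-jerk return
    vp_mean: float = 0.499       # target peak velocity draw, m/s
    vp_sd: float = 0.02
    vp_bounds: tuple = (0.45, 0.55)
    pos_noise_sd: float = 4e-4   # position measurement noise SD, m
    pre_roll_s: float = 0.25     # quiet time recorded before movement onset
    post_roll_s: float = 0.25    # quiet time after the planned return

    def __post_init__(self) -> None:
        if not self.lag_plateau > self.lag_soft:
            raise InvalidParameterError("lag_plateau must exceed lag_soft")
        if not self.theta_asc > self.theta_desc:
            raise InvalidParameterError(
                "hysteresis requires theta_asc > theta_desc"
            )
        for name in ("lag_sd", "amp_noise_frac", "pos_noise_sd", "bump_sd_ms"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.m_eff <= 0:
            raise InvalidParameterError("m_eff must be positive")
        if self.switch_inertia_trials < 0:
            raise InvalidParameterError("switch_inertia_trials must be >= 0")

    def theta(self, condition: str) -> float:
        return self.theta_asc if condition == "ascending" else self.theta_desc


# ---------------------------------------------------------------------------
# planned kinematics


def peak_velocity_factor(p: float, q: float) -> float:
    """Return c with ``v_peak = c * A / T`` for the bell ``v ∝ t^p (T-t)^q``.

    The min-jerk case (p = q = 2) gives the classical factor 1.875.
    """
    return p**p * q**q / ((p + q) ** (p + q) * _beta_fn(p + 1, q + 1))


def min_jerk_duration(amplitude: float, v_peak: float) -> float:
    """Duration of a min-jerk point-to-point segment with a given peak speed."""
    return peak_velocity_factor(2.0, 2.0) * amplitude / v_peak


def bell_profile(t, amplitude: float, duration: float, p: float = 2.0, q: float = 2.0):
    """Position, velocity and acceleration of one bell-velocity segment.

    ``v(t) = A t^p (T-t)^q / (T^{p+q+1} B(p+1, q+1))`` for ``0 <= t <= T``
    (zero outside), which integrates to the regularized incomplete beta
    function for position.  Peak velocity occurs at ``t = p T / (p + q)``.
    """
    t = np.asarray(t, dtype=float)
    T = float(duration)
    tau = np.clip(t / T, 0.0, 1.0)
    y = amplitude * _betainc(p + 1, q + 1, tau)
    norm = amplitude / (T * _beta_fn(p + 1, q + 1))
    v = norm * tau**p * (1.0 - tau) ** q
    with np.errstate(divide="ignore", invalid="ignore"):
        a = norm / T * (
            p * tau ** (p - 1) * (1.0 - tau) ** q
            - q * tau**p * (1.0 - tau) ** (q - 1)
        )
    a = np.where((tau <= 0.0) | (tau >= 1.0), 0.0, a)
    return y, v, a


def _plan_trajectory(vp_target: float, cp: ControllerParams, fs: float):
    """Planned home -> target -> home trajectory sampled at ``fs``."""
    A = cp.plan_amplitude
    p_a, q_a = cp.ascent_shape
    p_d, q_d = cp.descent_shape
    T_a = peak_velocity_factor(p_a, q_a) * A / vp_target
    T_d = peak_velocity_factor(p_d, q_d) * A / vp_target
    dt = 1.0 / fs
    n = int(round((cp.pre_roll_s + T_a + T_d + cp.post_roll_s) / dt)) + 1
    t = np.arange(n) * dt
    y = np.zeros(n)
    v = np.zeros(n)
    a = np.zeros(n)
    up = (t >= cp.pre_roll_s) & (t < cp.pre_roll_s + T_a)
    y_u, v_u, a_u = bell_profile(t[up] - cp.pre_roll_s, A, T_a, p_a, q_a)
    y[up], v[up], a[up] = y_u, v_u, a_u
    down = t >= cp.pre_roll_s + T_a
    y_d, v_d, a_d = bell_profile(t[down] - cp.pre_roll_s - T_a, A, T_d, p_d, q_d)
    y[down], v[down], a[down] = A - y_d, -v_d, -a_d
    return t, y, v, a


def simulate_kinematics(vp_target: float, fp: FieldParams, m_eff: float,
                        fs: float = FS_SIM, cp: ControllerParams | None = None):
    """Planned and realized kinematics of one trial at the simulation rate.

    Returns ``(t, y, v, a, a_plan)``.  The feedforward motor command
    compensates the *expected* field along the planned path,
    ``u(t) = a_plan(t) + F_exp(y_plan(t)) / m_eff``, so on real trials the
    compensation cancels the rendered force exactly and the realized
    trajectory equals the plan (the target is touched and the peak field
    force is the scheduled ``k (0.15 - y0)``).  On catch trials the same
    command meets no force: the deviation from the plan obeys
    ``e'' = F_exp(y_plan)/m - K e - B e'`` with a slow critically damped
    corrective servo (``K = fb_stiffness``, ``B = fb_damping``), so the
    catch trajectory overshoots the target by ~1-4 cm, its acceleration
    diverges from the real-trial acceleration shortly after (expected)
    force onset, and the hand is brought back to the plan by trial end.
    """
    cp = cp or ControllerParams()
    lo, hi = cp.vp_bounds
    if not lo <= vp_target <= hi:
        raise InvalidParameterError(
            f"target peak velocity {vp_target} outside [{lo}, {hi}] m/s"
        )
    t, y_plan, v_plan, a_plan = _plan_trajectory(vp_target, cp, fs)
    if not fp.is_catch:
        return t, y_plan.copy(), v_plan.copy(), a_plan.copy(), a_plan
    # catch: integrate the deviation driven by the uncancelled compensation
    f_comp = elastic_force(y_plan, fp.expected_field()) / m_eff
    dt = 1.0 / fs
    K, B = cp.fb_stiffness, cp.fb_damping
    n = len(t)
    e = np.zeros(n)
    ed = np.zeros(n)
    edd = np.zeros(n)
    ei = edi = 0.0
    for i in range(n - 1):
        eddi = f_comp[i] - K * ei - B * edi
        edd[i] = eddi
        edi = edi + eddi * dt
        ei = ei + edi * dt
        ed[i + 1] = edi
        e[i + 1] = ei
    edd[-1] = edd[-2]
    return t, y_plan + e, v_plan + ed, a_plan + edd, a_plan


# ---------------------------------------------------------------------------
# switched lag model


def lag_model(ln_k, cp: ControllerParams, regime: str, condition: str = "ascending"):
    """Grip-peak lag re (expected) impact, ms, for the given control regime.

    In the ``"soft"`` regime the lag rises linearly in ln(stiffness) from
    ``lag_soft`` at the softest scheduled field to ``lag_plateau`` at the
    condition's threshold (and extrapolates past it while the switch is
    pending); in the ``"stiff"`` regime the lag sits at the plateau.
    """
    ln_k = np.asarray(ln_k, dtype=float)
    if np.any(ln_k < LN_K_MIN - 1e-9) or np.any(ln_k > math.log(2800.0) + 1e-9):
        raise InvalidParameterError("ln stiffness outside the scheduled range")
    if regime == "stiff":
        out = np.full_like(ln_k, cp.lag_plateau)
    elif regime == "soft":
        theta = cp.theta(condition)
        slope = (cp.lag_plateau - cp.lag_soft) / (theta - LN_K_MIN)
        out = cp.lag_soft + slope * (ln_k - LN_K_MIN)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return out if out.ndim else float(out)


def trial_regimes(schedule: BlockSchedule, cp: ControllerParams) -> list:
    """Per-trial lag regime of one block under hysteretic switch inertia.

    Ascending blocks start in the ``soft`` regime and flip to ``stiff``
    ``switch_inertia_trials`` trials after the schedule first reaches
    ``theta_asc``; descending blocks start ``stiff`` and flip to ``soft``
    the same number of trials after first dropping below ``theta_desc``.
    """
    ln_ks = np.array([fp.ln_k_expected for fp in schedule.trials])
    n = len(ln_ks)
    if schedule.condition == "ascending":
        crossed = np.nonzero(ln_ks >= cp.theta_asc)[0]
        flip = crossed[0] + cp.switch_inertia_trials if crossed.size else n
        return ["soft" if i < flip else "stiff" for i in range(n)]
    crossed = np.nonzero(ln_ks < cp.theta_desc)[0]
    flip = crossed[0] + cp.switch_inertia_trials if crossed.size else n
    return ["stiff" if i < flip else "soft" for i in range(n)]


# ---------------------------------------------------------------------------
# grip force


def grip_profile(t, accel, fp: FieldParams, cp: ControllerParams,
                 condition: str, regime: str, t_impact: float,
                 rng: np.random.Generator | None = None):
    """Synthesize the grip-force channel of one trial.

    Returns ``(f_grip, truth_lag_ms)``.  The profile is a baseline plus an
    inertial component proportional to the positive part of the anticipated
    acceleration (the planned acceleration, which real trials realize
    exactly), low-passed at the muscular bandwidth and jittered in time by
    ``lag_sd`` — its first local peak is synchronized with the first
    acceleration peak — plus an anticipatory Gaussian bump centred
    ``lag_model(...) + N(0, lag_sd)`` ms after the (expected) impact, with
    inverted-U amplitude in ln(stiffness).  The construction is identical
    on catch trials (feedforward control), and the positive part vanishes
    through the impact region, so the bump's argmax is undistorted there.
    """
    rng = rng or np.random.default_rng()
    t = np.asarray(t, dtype=float)
    accel = np.asarray(accel, dtype=float)
    jitter = rng.normal(0.0, cp.lag_sd) / 1000.0 if cp.lag_sd > 0 else 0.0
    inertial = cp.inertial_gain * np.clip(
        np.interp(t - jitter, t, accel), 0.0, None
    )
    if cp.grip_lp_hz > 0:
        fs = 1.0 / (t[1] - t[0])
        inertial = zero_phase_lowpass(inertial, fs, cp.grip_lp_hz)
    theta = cp.theta(condition)
    ln_k = fp.ln_k_expected
    amp = cp.amp_peak * math.exp(-((ln_k - theta) ** 2) / (2.0 * cp.amp_width**2))
    if cp.amp_noise_frac > 0:
        amp *= max(0.0, 1.0 + cp.amp_noise_frac * rng.normal())
    truth_lag = float(lag_model(ln_k, cp, regime, condition))
    truth_lag += rng.normal(0.0, cp.lag_sd) if cp.lag_sd > 0 else 0.0
    centre = t_impact + truth_lag / 1000.0
    sd = cp.bump_sd_ms / 1000.0
    f_grip = cp.gf_baseline + inertial + amp * np.exp(-((t - centre) ** 2) / (2.0 * sd**2))
    return f_grip, truth_lag


# ---------------------------------------------------------------------------
# trials, participants, cohorts


@dataclass(frozen=True)
class TrialMeta:
    """Identifiers and ground truth carried by one simulated trial."""

    participant: int
    block: int                # 1-based block index within the session
    trial: int                # 1-based trial index within the block
    condition: str            # "ascending" | "descending"
    field: FieldParams
    regime: str               # lag regime used by the generator
    vp_target: float          # planned peak velocity, m/s
    truth_lag_ms: float       # lag actually used for the anticipatory bump
    t_impact_true: float      # (expected) impact time on the record grid, s


@dataclass(frozen=True)
class TrialSeries:
    """Uniformly sampled recording of one trial (500 Hz).

    ``y`` carries measurement noise as recorded; ``v`` and ``a`` are the
    generator's noise-free kinematics (the preprocessing chain re-derives
    both from ``y``).  ``f_load`` is the rendered elastic force, identically
    zero on catch trials.
    """

    t: np.ndarray
    y: np.ndarray
    v: np.ndarray
    a: np.ndarray
    f_load: np.ndarray
    f_grip: np.ndarray
    meta: TrialMeta

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("y", "v", "a", "f_load", "f_grip"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


def _draw_vp(rng: np.random.Generator, cp: ControllerParams) -> float:
    lo, hi = cp.vp_bounds
    for _ in range(1000):
        vp = rng.normal(cp.vp_mean, cp.vp_sd)
        if lo <= vp <= hi:
            return float(vp)
    return float(np.clip(cp.vp_mean, lo, hi))


def simulate_trial(fp: FieldParams, cp: ControllerParams, condition: str,
                   regime: str, rng: np.random.Generator,
                   participant: int = 0, block: int = 1, trial: int = 1,
                   fs: float = 500.0) -> TrialSeries:
    """Simulate one complete trial and decimate to the recording rate."""
    vp = _draw_vp(rng, cp)
    t_s, y_s, v_s, a_s, a_plan_s = simulate_kinematics(vp, fp, cp.m_eff, FS_SIM, cp)
    step = int(round(FS_SIM / fs))
    t, y, v, a, a_plan = (x[::step] for x in (t_s, y_s, v_s, a_s, a_plan_s))

    f_load = elastic_force(y, fp)
    if fp.is_catch:
        f_expected = elastic_force(y, fp.expected_field())
    else:
        f_expected = f_load
    if not np.any(f_expected > 0):
        raise InvalidParameterError("trial never enters the (expected) field")
    i_imp = int(np.argmax(f_expected))
    t_impact = float(t[i_imp])

    f_grip, truth_lag = grip_profile(t, a_plan, fp, cp, condition, regime,
                                     t_impact, rng)
    if cp.pos_noise_sd > 0:
        y = y + rng.normal(0.0, cp.pos_noise_sd, size=y.shape)
    meta = TrialMeta(participant=participant, block=block, trial=trial,
                     condition=condition, field=fp, regime=regime,
                     vp_target=vp, truth_lag_ms=truth_lag,
                     t_impact_true=t_impact)
    return TrialSeries(t=t, y=y, v=v.copy(), a=a.copy(),
                       f_load=np.asarray(f_load, dtype=float),
                       f_grip=f_grip, meta=meta)


def _block_conditions(order: str, n_blocks: int) -> list:
    half = n_blocks // 2
    first, second = ("ascending", "descending")
    if order == "desc-first":
        first, second = second, first
    elif order != "asc-first":
        raise ValueError(f"unknown order {order!r}")
    return [first] * half + [second] * (n_blocks - half)


def simulate_participant(participant: int, cp: ControllerParams,
                         order: str = "asc-first", n_blocks: int = 10,
                         fs: float = 500.0, seed=None) -> list:
    """Simulate one participant's session (default 10 blocks x 45 trials)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    block_seeds = ss.spawn(n_blocks)
    out = []
    for b, condition in enumerate(_block_conditions(order, n_blocks), start=1):
        bseed = block_seeds[b - 1]
        sched_seed, trial_seed = bseed.spawn(2)
        schedule = make_schedule(condition, seed=sched_seed)
        regimes = trial_regimes(schedule, cp)
        rng = np.random.default_rng(trial_seed)
        for i, fp in enumerate(schedule.trials, start=1):
            out.append(simulate_trial(fp, cp, condition, regimes[i - 1], rng,
                                      participant=participant, block=b,
                                      trial=i, fs=fs))
    return out


def cohort_orders(n_participants: int, order: str = "counterbalanced") -> list:
    """Block-order assignment per participant.

    ``"counterbalanced"`` alternates asc-first/desc-first, matching the
    study's roughly even split (10 vs 8 of 18).
    """
    if order in ("asc-first", "desc-first"):
        return [order] * n_participants
    if order != "counterbalanced":
        raise ValueError(f"unknown order {order!r}")
    return ["asc-first" if i % 2 == 0 else "desc-first"
            for i in range(n_participants)]


def iter_cohort(n_participants: int, cp: ControllerParams | None = None,
                order: str = "counterbalanced", n_blocks: int = 10,
                fs: float = 500.0, seed=None) -> Iterator[tuple]:
    """Yield ``(participant_id, [TrialSeries, ...])`` one participant at a time."""
    cp = cp or ControllerParams()
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(n_participants)
    orders = cohort_orders(n_participants, order)
    for pid in range(1, n_participants + 1):
        yield pid, simulate_participant(pid, cp, orders[pid - 1], n_blocks,
                                        fs, seeds[pid - 1])


def simulate_cohort(n_participants: int, cp: ControllerParams | None = None,
                    order: str = "counterbalanced", n_blocks: int = 10,
                    fs: float = 500.0, seed=None) -> list:
    """Simulate a full cohort and return all trials as a flat list.

    For large cohorts prefer :func:`iter_cohort`, which releases each
    participant's raw series after use.
    """
    trials = []
    for _, series in iter_cohort(n_participants, cp, order, n_blocks, fs, seed):
        trials.extend(series)
    return trials


def truth_table(trials: Sequence[TrialSeries]):
    """Ground-truth manifest of simulated trials as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for s in trials:
        m = s.meta
        rows.append({
            "participant": m.participant, "block": m.block, "trial": m.trial,
            "condition": m.condition, "is_catch": m.field.is_catch,
            "k_Npm": m.field.k, "y0_cm": m.field.y0_cm,
            "expected_k_Npm": m.field.expected_k,
            "expected_y0_cm": m.field.expected_y0 * 100.0,
            "ln_k_expected": m.field.ln_k_expected,
            "regime": m.regime, "vp_target_mps": m.vp_target,
            "truth_lag_ms": m.truth_lag_ms, "t_impact_true_s": m.t_impact_true,
        })
    return pd.DataFrame(rows)
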