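"""Experimental design: elastic force fields and block schedules.

The virtual object is a one-sided spring engaged above a boundary position
``y0``: the rendered force is ``F = k (y - y0)`` for ``y >= y0`` and zero
below, with a C1 quadratic blend of half-width ``w`` around the boundary so
the haptic device never renders a force-rate step.  A recording block is 45
upward reaches through such a field; stiffness and force onset co-vary on a
fixed linear onset grid (3 -> 14.5 cm in steps of 0.2875 cm), ascending over
41 trials and holding the stiffest field for the last four, or the exact
reverse.  Six trials per block are catch trials in which the field is
silently zeroed while the scheduled (k, y0) pair is retained as the
"expected" field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TARGET_POS_M",
    "FieldParams",
    "BlockSchedule",
    "elastic_force",
    "make_schedule",
    "mini_block_sizes",
    "mini_blocks",
    "ScheduleError",
    "InvalidParameterError",
]

#: Height of the target above home position, m.  The nominal peak field force
#: of a schedule entry is k * (TARGET_POS_M - y0).
TARGET_POS_M = 0.15

#: Onset grid used in the study: 3 cm to 14.5 cm in exact steps of 0.2875 cm.
Y0_MIN_CM = 3.0
Y0_MAX_CM = 14.5
Y0_STEP_CM = 0.2875

#: Default smoothing half-width of the force onset, m.
DEFAULT_W = 0.005


class InvalidParameterError(ValueError):
    """A field or controller parameter is outside its admissible range."""


class ScheduleError(ValueError):
    """The requested block schedule cannot be constructed."""


@dataclass(frozen=True)
class FieldParams:
    """One elastic force field (possibly a zeroed catch-trial field).

    Parameters
    ----------
    k : float
        Stiffness, N/m.  Zero on catch trials.
    y0 : float
        Force-onset position, m.  Zero on catch trials.
    w : float
        Smoothing half-width of the onset blend, m.
    is_catch : bool
        True if the field is silently disabled for this trial.
    expected_k, expected_y0 : float
        The scheduled field that *would* have been rendered.  Equal to
        (k, y0) on real trials; on catch trials they retain the scheduled
        values while (k, y0) are zero.
    """

    k: float
    y0: float
    w: float = DEFAULT_W
    is_catch: bool = False
    expected_k: float = field(default=math.nan)
    expected_y0: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise InvalidParameterError(f"stiffness must be >= 0, got {self.k}")
        if self.w < 0:
            raise InvalidParameterError(f"smoothing half-width must be >= 0, got {self.w}")
        if math.isnan(self.expected_k):
            object.__setattr__(self, "expected_k", self.k)
        if math.isnan(self.expected_y0):
            object.__setattr__(self, "expected_y0", self.y0)
        if self.is_catch:
            if self.k != 0.0 or self.y0 != 0.0:
                raise InvalidParameterError("catch trials must have k = y0 = 0")
        else:
            if not (Y0_MIN_CM - 1e-9 <= self.y0 * 100.0 <= Y0_MAX_CM + 1e-9):
                raise InvalidParameterError(
                    f"non-catch force onset must lie in [{Y0_MIN_CM}, {Y0_MAX_CM}] cm, "
                    f"got {self.y0 * 100.0:.4f} cm"
                )

    @property
    def y0_cm(self) -> float:
        return self.y0 * 100.0

    @property
    def f_max(self) -> float:
        """Nominal peak force of the scheduled field at the target, N."""
        return self.expected_k * (TARGET_POS_M - self.expected_y0)

    @property
    def ln_k_expected(self) -> float:
        """Natural log of the scheduled stiffness (defined for catch trials)."""
        return math.log(self.expected_k)

    def expected_field(self) -> "FieldParams":
        """The scheduled field as a renderable (non-catch) parameter set."""
        if not self.is_catch:
            return self
        return FieldParams(k=self.expected_k, y0=self.expected_y0, w=self.w)


def elastic_force(y, fp: FieldParams):
    """Rendered force of a one-sided elastic field, N.

    Zero below ``y0 - w``, the linear spring law ``k (y - y0)`` above
    ``y0 + w``, and the unique C1 quadratic blend
    ``k (y - y0 + w)^2 / (4 w)`` in between.  Monotone non-decreasing in
    ``y`` and continuously differentiable everywhere.

    Accepts scalars or arrays; catch-trial fields return zeros (use
    :meth:`FieldParams.expected_field` to evaluate the scheduled force).
    """
    if fp.k < 0:
        raise InvalidParameterError("negative stiffness")
    y = np.asarray(y, dtype=float)
    k, y0, w = fp.k, fp.y0, fp.w
    if fp.is_catch or k == 0.0:
        out = np.zeros_like(y)
        return out if out.ndim else float(out)
    if w == 0.0:
        out = k * np.clip(y - y0, 0.0, None)
    else:
        out = np.where(
            y <= y0 - w,
            0.0,
            np.where(y >= y0 + w, k * (y - y0), k * (y - y0 + w) ** 2 / (4.0 * w)),
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered 45-trial schedule of one block.

    ``trials`` holds one :class:`FieldParams` per trial (catch entries are
    already zeroed with the scheduled field retained as expected values);
    ``catch_indices`` are the 0-based positions of the 6 catch trials.
    """

    condition: str  # "ascending" | "descending"
    trials: tuple
    catch_indices: frozenset

    def __post_init__(self) -> None:
        if self.condition not in ("ascending", "descending"):
            raise ScheduleError(f"unknown condition {self.condition!r}")
        if len(self.trials) == 45 and len(self.catch_indices) != 6:
            raise ScheduleError("a 45-trial block must contain exactly 6 catch trials")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_real(self) -> int:
        return len(self.trials) - len(self.catch_indices)


def mini_block_sizes(n_trials: int = 45):
    """Mini-block partition of one block: [10, 5, 5, 5, 5, 5, 10]."""
    if n_trials != 45:
        raise ValueError(f"mini-blocks are defined for 45-trial blocks, got {n_trials}")
    return (10, 5, 5, 5, 5, 5, 10)


def mini_blocks(trial_indices) -> np.ndarray:
    """Mini-block label (1-7) for each 1-based trial index of a 45-trial block."""
    idx = np.asarray(trial_indices, dtype=int)
    if idx.size != 45 or np.any(np.sort(idx) != np.arange(1, 46)):
        raise ValueError("expected the 45 trial indices 1..45 of one block")
    edges = np.cumsum(mini_block_sizes(45))
    return np.searchsorted(edges, idx - 1, side="right") + 1


def mini_block_of(trial_index: int) -> int:
    """Mini-block label (1-7) of a single 1-based trial index."""
    if not 1 <= trial_index <= 45:
        raise ValueError(f"trial index must be in 1..45, got {trial_index}")
    edges = np.cumsum(mini_block_sizes(45))
    return int(np.searchsorted(edges, trial_index - 1, side="right")) + 1


def _onset_grid_cm(y0_min_cm: float, y0_max_cm: float, step_cm: float) -> np.ndarray:
    n_steps = (y0_max_cm - y0_min_cm) / step_cm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ScheduleError(
            f"onset grid [{y0_min_cm}, {y0_max_cm}] cm is not representable "
            f"at a step of {step_cm} cm"
        )
    n = int(round(n_steps)) + 1
    return y0_min_cm + step_cm * np.arange(n)


def stiffness_for_onset(y0_cm, y0_min_cm: float = Y0_MIN_CM, y0_max_cm: float = Y0_MAX_CM,
                        f_low: float = 4.0, f_high: float = 14.0):
    """Stiffness paired with a force onset, N/m.

    The peak field force at the target is linear in the onset position,
    from ``f_low`` at the shallowest onset to ``f_high`` at the deepest,
    and ``k = F_max / (0.15 m - y0)``; this reproduces the study's two
    printed extremes, 4/0.12 = 33.33 N/m and 14/0.005 = 2800 N/m.
    """
    y0_cm = np.asarray(y0_cm, dtype=float)
    f_max = f_low + (f_high - f_low) * (y0_cm - y0_min_cm) / (y0_max_cm - y0_min_cm)
    k = f_max / (TARGET_POS_M - y0_cm / 100.0)
    return k if k.ndim else float(k)


def _draw_catch_indices(rng: np.random.Generator, n_trials: int, n_catch: int,
                        mini_block_sizes) -> frozenset:
    """Catch positions: uniform without replacement, rejecting draws that
    leave any interior 5-trial mini-block without a real trial or place two
    catch trials on adjacent trials."""
    edges = np.cumsum([0, *mini_block_sizes])
    for _ in range(10_000):
        idx = np.sort(rng.choice(n_trials, size=n_catch, replace=False))
        if np.any(np.diff(idx) == 1):
            continue
        ok = True
        for lo, hi in zip(edges[:-1], edges[1:]):
            n_in = np.count_nonzero((idx >= lo) & (idx < hi))
            if n_in >= hi - lo:  # no real trial left in this mini-block
                ok = False
                break
        if ok:
            return frozenset(int(i) for i in idx)
    raise ScheduleError("could not place catch trials under the mini-block constraint")


def make_schedule(condition: str, n_trials: int = 45, n_catch: int = 6,
                  y0_min_cm: float = Y0_MIN_CM, y0_max_cm: float = Y0_MAX_CM,
                  step_cm: float = Y0_STEP_CM, f_low: float = 4.0, f_high: float = 14.0,
                  w: float = DEFAULT_W, seed=None) -> BlockSchedule:
    """Build one 45-trial block schedule.

    Ascending blocks run the 41 grid onsets in increasing-stiffness order and
    repeat the stiffest field for the 4 plateau trials; descending blocks are
    the exact reverse.  ``n_catch`` trials are then zeroed at positions drawn
    under the mini-block constraint (see :func:`_draw_catch_indices`).
    """
    if n_catch >= n_trials:
        raise ScheduleError("n_catch must be smaller than n_trials")
    grid_cm = _onset_grid_cm(y0_min_cm, y0_max_cm, step_cm)
    n_plateau = n_trials - len(grid_cm)
    if n_plateau < 0:
        raise ScheduleError(
            f"grid has {len(grid_cm)} onsets but the block only has {n_trials} trials"
        )
    onsets_cm = np.concatenate([grid_cm, np.full(n_plateau, grid_cm[-1])])
    if condition == "descending":
        onsets_cm = onsets_cm[::-1]
    elif condition != "ascending":
        raise ScheduleError(f"unknown condition {condition!r}")

    rng = np.random.default_rng(seed)
    sizes = mini_block_sizes(n_trials) if n_trials == 45 else (n_trials,)
    catch_idx = _draw_catch_indices(rng, n_trials, n_catch, sizes)

    trials = []
    for i, y0_cm in enumerate(onsets_cm):
        k = stiffness_for_onset(y0_cm, y0_min_cm, y0_max_cm, f_low, f_high)
        y0 = y0_cm / 100.0
        if i in catch_idx:
            fp = FieldParams(k=0.0, y0=0.0, w=w, is_catch=True,
                             expected_k=k, expected_y0=y0)
        else:
            fp = FieldParams(k=k, y0=y0, w=w)
        trials.append(fp)
    return BlockSchedule(condition=condition, trials=tuple(trials),
                         catch_indices=catch_idx)
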