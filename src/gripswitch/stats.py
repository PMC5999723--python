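"""Switching-detection statistics.

Estimators for the signatures of a switched feedforward grip-force
controller:

* the location of the grip-force-peak extremum on the ln(stiffness) axis
  (4th-order polynomial fit), whose ascending/descending difference is the
  hysteresis of the switch;
* participant-resampling bootstrap confidence intervals;
* continuous piecewise-linear ("hinge") regression of the grip/load peak lag
  against ln(stiffness) at a fixed breakpoint, compared with a single line
  by the Gaussian least-squares AIC;
* the iterative 20-ms-binned t-test locating the time at which real-trial
  and catch-trial accelerations diverge after force onset;
* the ln(stiffness) at which mean acceleration at force onset changes sign,
  and its across-participant correlation with the strategy-switch threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ExtremumFit",
    "PiecewiseFit",
    "BootstrapCI",
    "fit_extremum",
    "bootstrap_diff",
    "piecewise_fit",
    "aic_ls",
    "divergence_time",
    "acc_sign_threshold",
    "threshold_correlation",
]


# ---------------------------------------------------------------------------
# extremum of grip peak vs ln(stiffness)


@dataclass(frozen=True)
class ExtremumFit:
    """4th-order polynomial fit of grip-force peak against ln(stiffness)."""

    coeffs: np.ndarray        # power-basis coefficients, ascending order
    x_star: float             # argmax of the fit on the observed ln k range
    r2: float
    at_boundary: bool         # True if the maximum sits on the range edge
    condition: str = ""


def fit_extremum(ln_k, gf_peak, order: int = 4, condition: str = "") -> ExtremumFit:
    """Least-squares polynomial fit and its argmax over the observed range.

    The maximum is located on a 1e-3 grid over ``[min ln_k, max ln_k]`` and
    refined by the real roots of the fitted polynomial's derivative;
    boundary maxima are flagged rather than extrapolated.
    """
    x = np.asarray(ln_k, dtype=float)
    y = np.asarray(gf_peak, dtype=float)
    if len(np.unique(x)) < order + 2:
        raise ValueError(f"need at least {order + 2} distinct ln k values")
    poly = np.polynomial.Polynomial.fit(x, y, order)
    lo, hi = float(x.min()), float(x.max())
    grid = np.arange(lo, hi + 5e-4, 1e-3)
    grid[-1] = hi
    x_star = float(grid[np.argmax(poly(grid))])
    # refine with the stationary points of the quartic
    crit = [r.real for r in poly.deriv().roots()
            if abs(r.imag) < 1e-9 and lo <= r.real <= hi]
    candidates = np.array([lo, hi, x_star, *crit])
    x_star = float(candidates[np.argmax(poly(candidates))])
    resid = y - poly(x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    at_boundary = x_star in (lo, hi)
    return ExtremumFit(coeffs=poly.convert().coef, x_star=x_star, r2=r2,
                       at_boundary=at_boundary, condition=condition)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval of a paired statistic."""

    statistic: str
    estimate: float
    lo: float
    hi: float
    reps: int
    seed: int | None

    @property
    def excludes_zero(self) -> bool:
        return not (self.lo <= 0.0 <= self.hi)


def bootstrap_diff(sample_a, sample_b, reps: int = 10_000, seed=None,
                   statistic: str = "mean_diff", ci: float = 0.95) -> BootstrapCI:
    """Participant-resampling bootstrap CI for a paired two-sample statistic.

    Participants are resampled with replacement (pairs kept together).
    ``statistic`` is ``"mean_diff"`` (mean(a) - mean(b)) or
    ``"abs_mean_diff"`` (|mean(a) - mean(b)|, used for the low/high-stiffness
    slope comparison).  Percentile interval at the 2.5/97.5 quantiles for
    the default 95% level.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be equal-length 1-d paired arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 participants to bootstrap")
    if reps < 1000:
        raise ValueError("use at least 1000 bootstrap repetitions")

    def stat(av, bv):
        d = av.mean(axis=-1) - bv.mean(axis=-1)
        return np.abs(d) if statistic == "abs_mean_diff" else d

    if statistic not in ("mean_diff", "abs_mean_diff"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    boot = stat(a[idx], b[idx])
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(statistic=statistic, estimate=float(stat(a, b)),
                       lo=float(lo), hi=float(hi), reps=reps,
                       seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# hinge regression and AIC


@dataclass(frozen=True)
class PiecewiseFit:
    """Hinge (two-slope, fixed-breakpoint) fit vs a single line."""

    xb: float                 # breakpoint on the ln k axis
    s_lo: float               # slope below the breakpoint, ms per ln-unit
    s_hi: float               # slope above
    intercept: float          # fitted value at the breakpoint (continuous model)
    rss_piecewise: float
    rss_linear: float
    aic_piecewise: float
    aic_linear: float
    n: int
    continuous: bool = True

    @property
    def prefers_piecewise(self) -> bool:
        return self.aic_piecewise < self.aic_linear


def aic_ls(n: int, rss: float, p_mean_params: int, corrected: bool = False) -> float:
    """Gaussian least-squares AIC: ``n ln(rss/n) + 2 (p + 1)``.

    The residual variance counts as one estimated parameter on top of the
    ``p_mean_params`` mean parameters.  ``corrected=True`` applies the
    small-sample AICc correction.  ``rss == 0`` returns ``-inf`` with a
    warning (a saturated fit).
    """
    if n <= p_mean_params:
        raise ValueError("need more points than mean parameters")
    if rss < 0:
        raise ValueError("negative residual sum of squares")
    if rss == 0.0:
        warnings.warn("zero RSS: AIC is -inf (saturated fit)", RuntimeWarning,
                      stacklevel=2)
        return -math.inf
    k = p_mean_params + 1
    aic = n * math.log(rss / n) + 2.0 * k
    if corrected:
        if n - k - 1 <= 0:
            raise ValueError("AICc undefined: n <= k + 1")
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return aic


def piecewise_fit(ln_k, lag_ms, xb: float, continuous: bool = True,
                  corrected_aic: bool = False) -> PiecewiseFit:
    """Fit lag vs ln(stiffness) with a hinge at the fixed breakpoint ``xb``.

    The default continuous model is
    ``lag = b0 + s_lo (x - xb) [x < xb] + s_hi (x - xb) [x >= xb]``
    (3 mean parameters); ``continuous=False`` fits two unconstrained lines
    (4 mean parameters).  The single-line fit on the same points is returned
    alongside for the AIC comparison; the hinge nests the line, so
    ``rss_piecewise <= rss_linear`` always.
    """
    x = np.asarray(ln_k, dtype=float)
    y = np.asarray(lag_ms, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ln_k and lag_ms must be equal-length 1-d arrays")
    below, above = x < xb, x >= xb
    if below.sum() < 2 or above.sum() < 2:
        raise ValueError("need at least 2 points on each side of the breakpoint")
    n = x.size

    if continuous:
        X = np.column_stack([np.ones(n), np.where(below, x - xb, 0.0),
                             np.where(above, x - xb, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        b0, s_lo, s_hi = coef
        rss_pw = float(np.sum((y - X @ coef) ** 2))
        p_pw = 3
    else:
        X = np.column_stack([below.astype(float), np.where(below, x - xb, 0.0),
                             above.astype(float), np.where(above, x - xb, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        s_lo, s_hi = coef[1], coef[3]
        b0 = coef[2]
        rss_pw = float(np.sum((y - X @ coef) ** 2))
        p_pw = 4

    Xl = np.column_stack([np.ones(n), x - xb])
    coef_l, *_ = np.linalg.lstsq(Xl, y, rcond=None)
    rss_lin = float(np.sum((y - Xl @ coef_l) ** 2))
    rss_pw = min(rss_pw, rss_lin) if continuous else rss_pw  # guard numerics

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aic_pw = aic_ls(n, rss_pw, p_pw, corrected_aic)
        aic_lin = aic_ls(n, rss_lin, 2, corrected_aic)
    return PiecewiseFit(xb=float(xb), s_lo=float(s_lo), s_hi=float(s_hi),
                        intercept=float(b0), rss_piecewise=rss_pw,
                        rss_linear=rss_lin, aic_piecewise=aic_pw,
                        aic_linear=aic_lin, n=n, continuous=continuous)


# ---------------------------------------------------------------------------
# divergence of real vs catch acceleration


def divergence_time(acc_real: np.ndarray, acc_catch: np.ndarray, fs: float,
                    bin_ms: float = 20.0, alpha: float = 0.05,
                    sustain_ms: float = 150.0):
    """Earliest sustained divergence of two trial x time acceleration matrices.

    Both matrices must be aligned so column 0 is force onset.  Acceleration
    is averaged within consecutive ``bin_ms`` bins per trial; each bin gets
    a two-sample t-test (real vs catch rows).  The divergence time is the
    start, in ms after force onset, of the earliest bin from which
    ``p < alpha`` holds for all consecutive bins spanning at least
    ``sustain_ms``; ``None`` if no such run exists.
    """
    ar = np.atleast_2d(np.asarray(acc_real, dtype=float))
    ac = np.atleast_2d(np.asarray(acc_catch, dtype=float))
    if ar.shape[1] != ac.shape[1]:
        raise ValueError("real and catch matrices must share the time axis")
    if ar.shape[0] < 2 or ac.shape[0] < 2:
        raise ValueError("need at least 2 trials of each type")
    n_per_bin = max(1, int(round(bin_ms / 1000.0 * fs)))
    n_bins = ar.shape[1] // n_per_bin
    if n_bins == 0:
        raise ValueError("traces shorter than one bin")
    need = max(1, math.ceil(sustain_ms / bin_ms))

    def bin_means(m):
        return m[:, :n_bins * n_per_bin].reshape(m.shape[0], n_bins, n_per_bin).mean(axis=2)

    br, bc = bin_means(ar), bin_means(ac)
    pvals = np.array([
        sps.ttest_ind(br[:, j], bc[:, j], equal_var=False).pvalue
        for j in range(n_bins)
    ])
    sig = pvals < alpha
    for j in range(n_bins - need + 1):
        if sig[j:j + need].all():
            return j * bin_ms
    return None


# ---------------------------------------------------------------------------
# acceleration-sign threshold and its correlation with the switch


def acc_sign_threshold(ln_k, acc_at_onset):
    """ln(stiffness) where mean acceleration at force onset changes sign.

    Trials are grouped by ln(stiffness) level; the across-trial mean curve,
    ordered by ln(stiffness), is scanned for its first sign change, and the
    zero crossing is linearly interpolated between the two bracketing
    levels.  Returns ``None`` when the mean curve never changes sign.
    """
    x = np.asarray(ln_k, dtype=float)
    y = np.asarray(acc_at_onset, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no finite observations")
    levels = np.unique(x)
    means = np.array([y[x == lv].mean() for lv in levels])
    signs = np.sign(means)
    nz = signs != 0
    flips = np.nonzero(np.diff(signs[nz]) != 0)[0]
    if flips.size == 0:
        return None
    il = np.nonzero(nz)[0]
    i0, i1 = il[flips[0]], il[flips[0] + 1]
    x0, x1, m0, m1 = levels[i0], levels[i1], means[i0], means[i1]
    return float(x0 - m0 * (x1 - x0) / (m1 - m0))


def threshold_correlation(x_strategy, x_accsign):
    """Pearson correlation between per-participant switch estimates.

    Returns ``(r, p)`` for the strategy-switch threshold against the
    acceleration-sign threshold, two-sided.
    """
    a = np.asarray(x_strategy, dtype=float)
    b = np.asarray(x_accsign, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
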