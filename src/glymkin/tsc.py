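"""Kinetic descriptors of a time-signal curve.

Arrival time, time-to-maximum, maximum signal, area under the curve and a
mono-exponential decay rate, with the validity rules applied in the study:
the decay ``a * exp(-b*t)`` is fitted only to samples at least 90 min after
the curve maximum, and the fit is discarded when the maximum falls less
than 90 min before the end of acquisition, when fewer than 3 samples
remain, or when the fitted rate is not positive.

"Increased" in the arrival rule means strictly greater; three successive
pairwise increases starting at the reported sample.  The decay fit uses
absolute acquisition time (not time since peak), so the amplitude ``a`` is
window-dependent while the rate ``b`` is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from glymkin.io_core import TimeSignalCurve

__all__ = [
    "DecayFit",
    "TSCParameters",
    "arrival_time",
    "auc",
    "fit_decay",
    "parameterize",
    "peak",
]

#: Samples earlier than this after the curve maximum are excluded from the
#: decay fit; maxima closer than this to the end of acquisition invalidate it.
DECAY_LAG_MIN = 90.0


@dataclass
class DecayFit:
    a: float
    b: float
    valid: bool
    window: tuple[float, float] | None = None
    n_points: int = 0
    message: str = ""


@dataclass
class TSCParameters:
    """Per-curve kinetic descriptors with decay validity flag."""

    t_a: float | None
    t_max: float
    s_max: float
    auc: float
    a: float | None
    b: float | None
    decay_valid: bool
    fit_window: tuple[float, float] | None = None
    label: str = ""
    condition: str = ""
    animal_id: str = ""


def arrival_time(tsc: TimeSignalCurve) -> float | None:
    """Earliest time where the signal rises for three successive samples.

    Returns the time ``t_i`` of the first sample such that
    ``v[i+1] > v[i]``, ``v[i+2] > v[i+1]`` and ``v[i+3] > v[i+2]``; ``None``
    if no such sample exists (a legal outcome for flat or noisy curves).
    """
    v = tsc.values
    rises = np.diff(v) > 0
    for i in range(v.size - 3):
        if rises[i] and rises[i + 1] and rises[i + 2]:
            return float(tsc.times[i])
    return None


def peak(tsc: TimeSignalCurve) -> tuple[float, float]:
    """Global maximum value and its time; ties resolve to the earliest time."""
    i = int(np.argmax(tsc.values))
    return float(tsc.times[i]), float(tsc.values[i])


def auc(tsc: TimeSignalCurve, t_end: float = 360.0, strict: bool = True) -> float:
    """Trapezoidal integral of the curve over ``[t_start, t_end]`` (%.min).

    If the grid extends beyond ``t_end`` the curve is clipped with linear
    interpolation at ``t_end``.  If the grid ends before ``t_end``:
    ``strict=True`` raises, otherwise the integral runs to the last sample.
    """
    times, values = tsc.times, tsc.values
    if t_end > times[-1]:
        if strict:
            raise ValueError(
                f"t_end={t_end} min lies beyond the last sample at {times[-1]} min"
            )
        t_end = float(times[-1])
    keep = times <= t_end
    t_clip = times[keep]
    v_clip = values[keep]
    if t_clip[-1] < t_end:
        t_clip = np.append(t_clip, t_end)
        v_clip = np.append(v_clip, np.interp(t_end, times, values))
    return float(np.trapezoid(v_clip, t_clip))


def fit_decay(tsc: TimeSignalCurve, min_points: int = 3) -> DecayFit:
    """Least-squares mono-exponential decay fit over the late window.

    Fits ``a * exp(-b*t)`` (unweighted, absolute time) to samples with
    ``t >= t_max + 90`` min.  Initialization comes from a log-linear
    regression on the positive window samples; non-positive samples are
    excluded from initialization only, never from the fit itself.
    """
    t_max, _ = peak(tsc)
    t_end = float(tsc.times[-1])
    if t_max > t_end - DECAY_LAG_MIN:
        return DecayFit(
            np.nan, np.nan, False,
            message=f"maximum at {t_max:.1f} min is less than "
            f"{DECAY_LAG_MIN:.0f} min before end of acquisition",
        )
    in_window = tsc.times >= t_max + DECAY_LAG_MIN
    t_w = tsc.times[in_window]
    v_w = tsc.values[in_window]
    window = (float(t_w[0]), t_end) if t_w.size else None
    if t_w.size < min_points:
        return DecayFit(
            np.nan, np.nan, False, window=window, n_points=int(t_w.size),
            message=f"only {t_w.size} samples in the fit window",
        )

    pos = v_w > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t_w[pos], np.log(v_w[pos]), 1)
        a0, b0 = float(np.exp(intercept)), float(-slope)
    else:
        a0, b0 = max(float(np.max(v_w)), 1e-6), 1e-3
    if b0 <= 0:
        b0 = 1e-4

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda t, a, b: a * np.exp(-b * t),
                t_w, v_w, p0=(a0, b0), maxfev=10000,
            )
    except RuntimeError as exc:
        return DecayFit(
            np.nan, np.nan, False, window=window, n_points=int(t_w.size),
            message=f"optimizer did not converge: {exc}",
        )
    a_hat, b_hat = float(popt[0]), float(popt[1])
    if b_hat <= 0:
        return DecayFit(
            a_hat, b_hat, False, window=window, n_points=int(t_w.size),
            message="fitted decay rate is not positive",
        )
    return DecayFit(a_hat, b_hat, True, window=window, n_points=int(t_w.size))


def parameterize(tsc: TimeSignalCurve, t_end: float = 360.0, strict_auc: bool = False) -> TSCParameters:
    """All kinetic descriptors of one curve in a single record."""
    t_max, s_max = peak(tsc)
    decay = fit_decay(tsc)
    return TSCParameters(
        t_a=arrival_time(tsc),
        t_max=t_max,
        s_max=s_max,
        auc=auc(tsc, t_end=t_end, strict=strict_auc),
        a=decay.a if decay.valid else None,
        b=decay.b if decay.valid else None,
        decay_valid=decay.valid,
        fit_window=decay.window,
        label=tsc.label,
        condition=tsc.condition,
        animal_id=tsc.animal_id,
    )
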