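"""Mono-exponential ADC estimation and ROI percent-change statistics.

``fit_adc`` fits ``S(b) = S0 * exp(-b * ADC)`` to a multi-b series by
weighted log-linear regression (weights proportional to S^2, the standard
variance-stabilizing choice for log-transformed magnitude data); an
unweighted nonlinear fit is available behind a flag.  With exactly two
b-values either route reduces to the closed form
``ADC = ln(S1/S2) / (b2 - b1)``.

``aqueduct_flow_surrogate`` computes a per-voxel pseudo-ADC from a single
diffusion-weighted shell against a reference image.  In the aqueduct this
attenuation mixes flow and diffusion, so the output is labeled a
flow-sensitized *magnitude* surrogate — directionality cannot be resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AdcFit",
    "RoiChange",
    "aqueduct_flow_surrogate",
    "fit_adc",
    "percent_change",
]

#: The study's 9-point diffusion-weighting scheme (s/mm^2).
DTI_B_VALUES = np.array([10, 200, 400, 600, 800, 1000, 1200, 1400, 1500], dtype=float)


@dataclass
class AdcFit:
    adc: float  # mm^2/s
    s0: float
    valid: bool = True
    message: str = ""


@dataclass
class RoiChange:
    """Percent change of an ROI statistic from its baseline-condition value."""

    baseline_value: float
    condition_value: float
    percent_change: float


def fit_adc(b_values, signals, weighted: bool = True) -> AdcFit:
    """Mono-exponential fit of ROI signal versus b-value.

    Parameters
    ----------
    b_values : array-like
        Diffusion weightings in s/mm^2, strictly increasing, >= 2 values.
    signals : array-like
        Positive mean ROI signals, one per b-value.
    weighted : bool
        Log-domain weighted linear regression (default) versus unweighted
        nonlinear least squares.

    A negative fitted ADC is returned but flagged invalid.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.ndim != 1 or b.shape != s.shape:
        raise ValueError("b_values and signals must be 1-D and the same length")
    if b.size < 2 or np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    if not np.all(np.diff(b) > 0):
        raise ValueError("b_values must be strictly increasing")
    if np.any(s <= 0):
        raise ValueError("signals must be positive for a mono-exponential fit")

    if weighted:
        # ln S = ln S0 - b*ADC, weights ~ S (np.polyfit squares the weights)
        slope, intercept = np.polyfit(b, np.log(s), 1, w=s)
        adc, s0 = -float(slope), float(np.exp(intercept))
    else:
        slope0, icpt0 = np.polyfit(b, np.log(s), 1)
        popt, _ = curve_fit(
            lambda bb, s0_, adc_: s0_ * np.exp(-adc_ * bb),
            b, s, p0=(np.exp(icpt0), -slope0), maxfev=10000,
        )
        s0, adc = float(popt[0]), float(popt[1])
    if adc < 0:
        return AdcFit(adc, s0, valid=False, message="fitted ADC is negative")
    return AdcFit(adc, s0)


def aqueduct_flow_surrogate(s_ref, s_b, b: float, mask=None) -> float:
    """ROI-mean pseudo-ADC from one diffusion shell against a reference.

    Per voxel ``ln(S_ref / S_b) / b``, averaged over the ROI (the whole
    array when ``mask`` is None).  The value reflects signal attenuation
    from flow plus diffusion: a flow-sensitized magnitude surrogate.
    """
    s_ref = np.asarray(s_ref, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if s_ref.shape != s_b.shape:
        raise ValueError("reference and diffusion-weighted images differ in shape")
    if b <= 0:
        raise ValueError("b must be positive")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        s_ref, s_b = s_ref[mask], s_b[mask]
    if s_ref.size == 0:
        raise ValueError("ROI is empty")
    if np.any(s_ref <= 0) or np.any(s_b <= 0):
        raise ValueError("signals must be positive")
    return float(np.mean(np.log(s_ref / s_b) / b))


def percent_change(baseline: float, value: float) -> RoiChange:
    """Relative change from the baseline-condition value, in percent."""
    if baseline <= 0:
        raise ValueError("baseline value must be positive")
    return RoiChange(
        baseline_value=float(baseline),
        condition_value=float(value),
        percent_change=100.0 * (value - baseline) / baseline,
    )
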