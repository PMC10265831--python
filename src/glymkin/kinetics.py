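"""Two-compartment exchange kinetics: rate fitting, volumes and the NER.

The exchange between an outer envelope and an enclosed inner compartment is
described by

    dI_in/dt = k1 * I_out(t) - k2 * I_in(t),   I_in(0) = 0

whose unique causal solution is the convolution

    I_in(t) = k1 * int_0^t exp(-k2 (t - l)) * I_out(l) dl.

``forward_model`` evaluates this convolution *exactly* for a sampled outer
curve interpreted as piecewise linear (an exponential-integrator
recurrence).  Plain trapezoidal quadrature of the kernel is avoided: at
coarse frame spacing its error reaches several percent, while the
piecewise-linear solution is limited only by the sampling of I_out and
matches independent ODE integration to ~1e-8.

Rates are estimated by minimizing the Euclidean norm of the residual over
the sampled time points.  For fixed ``k2`` the optimal ``k1`` is a linear
least-squares coefficient, so the search is a profiled 1-D scan over a
log-spaced ``k2`` grid followed by local refinement.  The search space is
restricted to nonnegative rates by default (negative rates are unphysical
and make the net exchange ratio sign-indeterminate); a flag lifts the
bound for replication studies.

Derived quantities: the total volumes ``V_out``/``V_in`` are the areas
under the curves up to the end of the experiment (last acquired frame),
the exchanged volumes are ``k1*V_out`` and ``k2*V_in``, and the net
exchange ratio is ``NER = V_in_to_out / V_out_to_in``.  Units of V are
arbitrary (signal x time), reported as "a.u.".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from glymkin.geometry import CompartmentPair, compartment_curves, split_region
from glymkin.io_core import Dynamic4D, LabelVolume, TimeSignalCurve

__all__ = [
    "ExchangeFit",
    "ThicknessRecord",
    "ThicknessSearchResult",
    "cohort_qc_thresholds",
    "compute_volumes",
    "fit_exchange_rates",
    "forward_model",
    "qc_gate",
    "thickness_search",
]

#: Default coarse search interval for both rates (1/min).
K_BOUNDS = (1e-5, 1.0)


@dataclass
class ExchangeFit:
    """Estimated exchange rates with model curve, volumes and NER."""

    k1: float
    k2: float
    i_in_sol: np.ndarray | None
    residual: float
    v_out: float = np.nan
    v_in: float = np.nan
    v_out_to_in: float = np.nan
    v_in_to_out: float = np.nan
    ner: float = np.nan
    usable: bool = True
    message: str = ""


def forward_model(k1: float, k2: float, times, i_out) -> np.ndarray:
    """Model inner curve ``k1 * int_0^t exp(-k2(t-l)) I_out(l) dl``.

    ``i_out`` may be a :class:`TimeSignalCurve` or an array sampled on
    ``times``.  The convolution is evaluated exactly for the
    piecewise-linear interpolant of the samples, via the stable recurrence

        J_i = exp(-k2 dt_i) * J_{i-1} + (segment integral),

    so the result is machine-precision for piecewise-linear inputs (e.g. a
    step input reproduces the closed form ``(k1/k2)(1 - exp(-k2 t))``).
    """
    if isinstance(i_out, TimeSignalCurve):
        if times is None:
            times = i_out.times
        i_out = i_out.values
    times = np.asarray(times, dtype=float)
    f = np.asarray(i_out, dtype=float)
    if times.shape != f.shape:
        raise ValueError("times and outer values must have the same shape")
    n = times.size
    out = np.zeros(n)
    for i in range(1, n):
        dt = times[i] - times[i - 1]
        f0, f1 = f[i - 1], f[i]
        a = k2 * dt
        if abs(a) < 1e-12:
            decay = 1.0
            inc = 0.5 * dt * (f0 + f1)
        else:
            decay = np.exp(-a)
            i0 = (1.0 - decay) / k2          # int_0^dt e^{-k2(dt-s)} ds
            i1 = (dt - i0) / (k2 * dt)       # int_0^dt e^{-k2(dt-s)} s/dt ds
            inc = f0 * i0 + (f1 - f0) * i1
        out[i] = decay * out[i - 1] + inc
    return k1 * out


def _profiled_objective(k2: float, times, f_out, y_in, nonneg: bool) -> tuple[float, float]:
    """Optimal k1 and residual norm for a fixed k2 (linear least squares)."""
    basis = forward_model(1.0, k2, times, f_out)
    denom = float(basis @ basis)
    if denom <= 0:
        return 0.0, float(np.linalg.norm(y_in))
    k1 = float(basis @ y_in) / denom
    if nonneg and k1 < 0:
        k1 = 0.0
    return k1, float(np.linalg.norm(y_in - k1 * basis))


def fit_exchange_rates(
    pair_or_out,
    i_in: TimeSignalCurve | None = None,
    k_bounds: tuple[float, float] = K_BOUNDS,
    grid_size: int = 80,
    nonneg: bool = True,
) -> ExchangeFit:
    """Estimate (k1, k2) minimizing ``||I_in - forward_model(k1,k2,I_out)||_2``.

    Accepts a :class:`CompartmentPair` or two curves on one grid.  The
    objective is the Euclidean norm over the sampled values (no time
    weighting).  For each candidate ``k2`` on a coarse log-spaced grid the
    optimal ``k1`` is computed in closed form; the best grid cell is then
    refined by bounded scalar minimization.  Degenerate cases (flat-zero
    inner curve) report ``k1 = 0`` with an undefined ``k2`` and
    ``usable=False``.
    """
    if isinstance(pair_or_out, CompartmentPair):
        pair = pair_or_out
        if not pair.usable or pair.i_in is None:
            return ExchangeFit(
                np.nan, np.nan, None, np.nan, usable=False,
                message=pair.message or "degenerate compartment pair",
            )
        i_out, i_in = pair.i_out, pair.i_in
    else:
        i_out = pair_or_out
        if i_in is None:
            raise TypeError("fit_exchange_rates needs a pair or two curves")
    if not np.array_equal(i_out.times, i_in.times):
        raise ValueError("outer and inner curves must share one time grid")

    times = i_out.times
    f_out = i_out.values
    y_in = i_in.values

    if not np.any(y_in != 0):
        fit = ExchangeFit(
            0.0, np.nan, np.zeros_like(y_in), 0.0, usable=False,
            message="inner curve is identically zero: k2 is a degenerate direction",
        )
        return _attach_volumes(fit, times, f_out, y_in)

    lo, hi = k_bounds
    k2_grid = np.geomspace(lo, hi, grid_size)
    residuals = np.empty(grid_size)
    k1s = np.empty(grid_size)
    for j, k2 in enumerate(k2_grid):
        k1s[j], residuals[j] = _profiled_objective(k2, times, f_out, y_in, nonneg)
    best = int(np.argmin(residuals))

    bracket_lo = k2_grid[max(best - 1, 0)]
    bracket_hi = k2_grid[min(best + 1, grid_size - 1)]
    result = minimize_scalar(
        lambda logk2: _profiled_objective(np.exp(logk2), times, f_out, y_in, nonneg)[1],
        bounds=(np.log(bracket_lo), np.log(bracket_hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    k2_hat = float(np.exp(result.x))
    k1_hat, res = _profiled_objective(k2_hat, times, f_out, y_in, nonneg)
    if res > residuals[best]:  # refinement must never be worse than the grid
        k2_hat, k1_hat, res = float(k2_grid[best]), float(k1s[best]), float(residuals[best])

    model = forward_model(k1_hat, k2_hat, times, f_out)
    fit = ExchangeFit(k1_hat, k2_hat, model, float(res))
    return _attach_volumes(fit, times, f_out, y_in)


def compute_volumes(times, i_out, i_in, k1: float, k2: float):
    """Curve volumes, exchanged volumes and NER from fitted rates.

    ``V_out``/``V_in`` are trapezoidal integrals over the full experiment;
    ``V_out_to_in = k1*V_out``; ``V_in_to_out = k2*V_in``;
    ``NER = V_in_to_out / V_out_to_in`` (nan when the denominator is 0).
    """
    times = np.asarray(times, dtype=float)
    v_out = float(np.trapezoid(np.asarray(i_out, float), times))
    v_in = float(np.trapezoid(np.asarray(i_in, float), times))
    v_oi = k1 * v_out
    v_io = k2 * v_in
    ner = v_io / v_oi if v_oi != 0 else np.nan
    return v_out, v_in, v_oi, v_io, ner


def _attach_volumes(fit: ExchangeFit, times, f_out, y_in) -> ExchangeFit:
    k1 = fit.k1 if np.isfinite(fit.k1) else 0.0
    k2 = fit.k2 if np.isfinite(fit.k2) else 0.0
    v_out, v_in, v_oi, v_io, ner = compute_volumes(times, f_out, y_in, k1, k2)
    fit.v_out, fit.v_in = v_out, v_in
    fit.v_out_to_in, fit.v_in_to_out = v_oi, v_io
    fit.ner = ner
    if v_oi == 0:
        fit.usable = False
        if not fit.message:
            fit.message = "V_out_to_in is zero: NER undefined"
        fit.ner = np.nan
    return fit


def qc_gate(fit: ExchangeFit, min_v_out: float, min_v_in: float | None = None) -> ExchangeFit:
    """Flag a fit unusable when either curve volume falls below a threshold.

    Mirrors the exclusion of low-CSF-formation conditions whose tracer
    volumes were too small for reliable rate estimates.  Only the flag and
    message change; fitted values are untouched.
    """
    if min_v_in is None:
        min_v_in = min_v_out
    gated = replace(fit)
    if fit.v_out < min_v_out or fit.v_in < min_v_in:
        gated.usable = False
        gated.message = (
            f"tracer volumes too small (V_out={fit.v_out:.3g}, "
            f"V_in={fit.v_in:.3g}; thresholds {min_v_out:.3g}/{min_v_in:.3g})"
        )
    return gated


def cohort_qc_thresholds(fits, fraction: float = 0.05) -> tuple[float, float]:
    """Volume thresholds as a fraction of the cohort medians (default 5%)."""
    v_outs = np.array([f.v_out for f in fits], dtype=float)
    v_ins = np.array([f.v_in for f in fits], dtype=float)
    return fraction * float(np.nanmedian(v_outs)), fraction * float(np.nanmedian(v_ins))


@dataclass
class ThicknessRecord:
    s: int
    n_outer: int
    n_inner: int
    fit: ExchangeFit | None
    deviation: float = np.nan
    deviation_pct: float = np.nan
    usable: bool = True
    message: str = ""


@dataclass
class ThicknessSearchResult:
    """Per-thickness deviations and the optimal shell thickness."""

    records: list[ThicknessRecord] = field(default_factory=list)
    optimal_s: int | None = None

    def deviations(self) -> dict[int, float]:
        return {r.s: r.deviation_pct for r in self.records if r.usable}


def thickness_search(
    dyn: Dynamic4D,
    lab: LabelVolume,
    region_id: int,
    s_range,
    connectivity: int = 6,
    aggregate: str = "sum",
    **fit_kwargs,
) -> ThicknessSearchResult:
    """Fit the exchange model at every shell thickness and pick the best.

    For each ``s`` the region is split, compartment curves aggregated and
    the model fitted; the deviation ``||I_in - I_in_sol||_2`` is recorded,
    also as a percentage of ``||I_in||_2`` (the scale-free form used to
    compare thicknesses).  The optimal ``s`` minimizes the percentage
    deviation; ties resolve to the smallest ``s``.  Degenerate splits
    (empty inner compartment) are excluded with a note.
    """
    s_values = [int(s) for s in s_range]
    if not s_values:
        raise ValueError("s_range must be nonempty")
    out = ThicknessSearchResult()
    for s in s_values:
        outer, inner = split_region(lab, region_id, s, connectivity=connectivity)
        pair = compartment_curves(
            dyn, outer, inner, region_id=region_id, s=s, aggregate=aggregate
        )
        if not pair.usable:
            out.records.append(
                ThicknessRecord(s, pair.n_outer, pair.n_inner, None,
                                usable=False, message=pair.message)
            )
            continue
        fit = fit_exchange_rates(pair, **fit_kwargs)
        norm_in = float(np.linalg.norm(pair.i_in.values))
        pct = 100.0 * fit.residual / norm_in if norm_in > 0 else np.nan
        out.records.append(
            ThicknessRecord(
                s, pair.n_outer, pair.n_inner, fit,
                deviation=fit.residual, deviation_pct=pct,
                usable=np.isfinite(pct),
            )
        )
    usable = [r for r in out.records if r.usable]
    if not usable:
        raise ValueError("no thickness in the range produced a usable split")
    best = min(usable, key=lambda r: (r.deviation_pct, r.s))
    out.optimal_s = best.s
    return out
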