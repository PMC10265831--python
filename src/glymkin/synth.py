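"""Synthetic cohorts and voxelized phantoms with planted kinetic ground truth.

The input-function family is a gamma variate — the study data show a
delayed rise, a peak and a slow decay, but publish no quantitative input
shape, so the gamma variate is this module's convention (documented, not
derived from data).  Inner-compartment curves are generated by integrating
the two-compartment exchange ODE

    dI_in/dt = k1 * I_out(t) - k2 * I_in(t),  I_in(0) = 0

with a classical fixed-step 4th-order Runge-Kutta scheme on a refined grid
(piecewise-linear forcing).  This is deliberately a different numerical
route than the convolution solution in :mod:`glymkin.kinetics`, so the two
can cross-validate each other.

Noise model: additive Gaussian on percent-change values (magnitude MRI
noise at high SNR is near-Gaussian).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from glymkin.io_core import Dynamic4D, LabelVolume, TimeSignalCurve

__all__ = [
    "AnimalSpec",
    "CONDITION_PRESETS",
    "SyntheticCohort",
    "build_shell_phantom",
    "default_times",
    "gamma_variate",
    "gamma_variate_input",
    "generate_cohort",
    "generate_inner_from_outer",
    "synthetic_calcium_trace",
]


@dataclass(frozen=True)
class AnimalSpec:
    """Planted per-animal parameters for cohort generation.

    ``t0`` (min), ``amplitude`` (%), ``alpha`` (shape) and ``tau`` (min)
    parameterize the gamma-variate input; ``k1``/``k2`` (1/min) are the
    planted exchange rates; ``noise_sd`` is the additive Gaussian noise SD
    in percent units.
    """

    condition: str = ""
    t0: float = 20.0
    amplitude: float = 30.0
    alpha: float = 2.0
    tau: float = 40.0
    k1: float = 0.02
    k2: float = 0.012
    noise_sd: float = 0.0
    seed: int = 0
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.amplitude <= 0 or self.tau <= 0 or self.alpha <= 0:
            raise ValueError("amplitude, tau and alpha must be > 0")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Illustrative per-condition presets (NOT measured values).  MED-like
#: conditions arrive early with high amplitude and faster inner->outer
#: exchange (planted NER near 0.96); ISO+MED keeps the arrival but has a
#: smaller k2 (planted NER near 0.94); AZE variants arrive late with low
#: amplitude.
CONDITION_PRESETS: dict[str, dict] = {
    "MED": dict(t0=15.0, amplitude=35.0, alpha=2.0, tau=40.0, k1=0.030, k2=0.0180, noise_sd=0.5),
    "ISO+MED": dict(t0=17.0, amplitude=33.0, alpha=2.0, tau=45.0, k1=0.028, k2=0.0167, noise_sd=0.5),
    "MED+AZE": dict(t0=60.0, amplitude=18.0, alpha=2.5, tau=50.0, k1=0.022, k2=0.0398, noise_sd=0.5),
    "ISO": dict(t0=45.0, amplitude=8.0, alpha=2.0, tau=60.0, k1=0.010, k2=0.008, noise_sd=0.5),
    "ISO+AZE": dict(t0=90.0, amplitude=5.0, alpha=2.5, tau=60.0, k1=0.008, k2=0.006, noise_sd=0.5),
    "ISO+MED+AZE": dict(t0=80.0, amplitude=6.0, alpha=2.5, tau=55.0, k1=0.008, k2=0.006, noise_sd=0.5),
}


def default_times(n_frames: int = 40, duration_min: float = 360.0) -> np.ndarray:
    """A 40-frame acquisition grid over 6 h starting at the baseline scan."""
    return np.linspace(0.0, duration_min, n_frames)


def gamma_variate(t, t0: float, amplitude: float, alpha: float, tau: float):
    """Gamma-variate input evaluated at ``t`` (scalar or array).

    ``A * ((t - t0)/(alpha*tau))**alpha * exp(alpha - (t - t0)/tau)`` for
    ``t > t0``, else 0.  The peak value is exactly ``A`` at
    ``t = t0 + alpha*tau``.
    """
    t = np.asarray(t, dtype=float)
    x = t - t0
    with np.errstate(invalid="ignore"):
        out = np.where(
            x > 0,
            amplitude * (np.maximum(x, 0.0) / (alpha * tau)) ** alpha
            * np.exp(alpha - np.maximum(x, 0.0) / tau),
            0.0,
        )
    return out if out.ndim else float(out)


def gamma_variate_input(
    t0: float, amplitude: float, alpha: float, tau: float, times, **meta
) -> TimeSignalCurve:
    """Sample a gamma-variate input function on ``times`` as a curve."""
    if amplitude <= 0 or tau <= 0 or alpha <= 0:
        raise ValueError("amplitude, tau and alpha must be > 0")
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    times = np.asarray(times, dtype=float)
    return TimeSignalCurve(times, gamma_variate(times, t0, amplitude, alpha, tau), **meta)


def generate_inner_from_outer(
    i_out: TimeSignalCurve, k1: float, k2: float, refine: int = 10
) -> TimeSignalCurve:
    """Integrate the exchange ODE to obtain the inner-compartment curve.

    ``dI_in/dt = k1*I_out - k2*I_in`` with ``I_in(0) = 0`` is integrated by
    classical RK4 on a grid refined ``refine``-fold between the curve's
    samples, treating the sampled outer curve as piecewise linear, and is
    then sampled back onto the curve's time grid.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("k1 and k2 must be >= 0")
    if refine < 1:
        raise ValueError("refine must be >= 1")
    times = i_out.times
    pieces = [
        np.linspace(times[i - 1], times[i], refine + 1)[:-1]
        for i in range(1, times.size)
    ]
    tfine = np.concatenate(pieces + [times[-1:]])
    ffine = np.interp(tfine, times, i_out.values)
    y = np.zeros(tfine.size)
    for i in range(1, tfine.size):
        h = tfine[i] - tfine[i - 1]
        f0, f1 = ffine[i - 1], ffine[i]
        fm = 0.5 * (f0 + f1)  # piecewise-linear forcing: midpoint = average
        yi = y[i - 1]
        a1 = k1 * f0 - k2 * yi
        a2 = k1 * fm - k2 * (yi + 0.5 * h * a1)
        a3 = k1 * fm - k2 * (yi + 0.5 * h * a2)
        a4 = k1 * f1 - k2 * (yi + h * a3)
        y[i] = yi + h / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
    idx = np.searchsorted(tfine, times)
    return i_out.with_values(y[idx], label="inner")


@dataclass
class SyntheticCohort:
    """Generated per-animal curves alongside their planted parameters.

    ``outer``/``inner`` carry the noisy observed curves; ``clean_outer`` /
    ``clean_inner`` the noise-free models used to plant ground truth.
    Regenerating with the same seed reproduces values bit-identically.
    """

    specs: list[AnimalSpec]
    times: np.ndarray
    outer: list[TimeSignalCurve] = field(default_factory=list)
    inner: list[TimeSignalCurve] = field(default_factory=list)
    clean_outer: list[TimeSignalCurve] = field(default_factory=list)
    clean_inner: list[TimeSignalCurve] = field(default_factory=list)

    def planted_ner(self, index: int) -> float:
        """NER implied by the planted rates and noise-free curves."""
        spec = self.specs[index]
        v_out = np.trapezoid(self.clean_outer[index].values, self.times)
        v_in = np.trapezoid(self.clean_inner[index].values, self.times)
        return (spec.k2 * v_in) / (spec.k1 * v_out)


def generate_cohort(specs, times, seed: int = 0) -> SyntheticCohort:
    """Generate a cohort of noisy outer/inner curve pairs on a shared grid.

    Per animal the outer curve is the gamma-variate input plus Gaussian
    noise, and the inner curve is the ODE response to the *noise-free*
    outer plus independent Gaussian noise.  All randomness derives from
    ``seed`` combined with each spec's own seed, so cohorts are
    deterministic and animals are independent.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one animal spec")
    times = np.asarray(times, dtype=float)
    cohort = SyntheticCohort(specs=specs, times=times)
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, spec.seed, i]))
        meta = dict(condition=spec.condition, animal_id=spec.animal_id or f"a{i:02d}")
        clean_out = gamma_variate_input(
            spec.t0, spec.amplitude, spec.alpha, spec.tau, times,
            label="outer", **meta,
        )
        clean_in = generate_inner_from_outer(clean_out, spec.k1, spec.k2)
        clean_in = clean_in.with_values(clean_in.values, label="inner")
        noisy_out = clean_out.with_values(
            clean_out.values + rng.normal(0.0, spec.noise_sd, times.size)
        )
        noisy_in = clean_in.with_values(
            clean_in.values + rng.normal(0.0, spec.noise_sd, times.size)
        )
        cohort.clean_outer.append(clean_out)
        cohort.clean_inner.append(clean_in)
        cohort.outer.append(noisy_out)
        cohort.inner.append(noisy_in)
    return cohort


def cohort_from_presets(
    condition: str,
    n_animals: int,
    times,
    seed: int = 0,
    jitter: float = 0.05,
    overrides: dict | None = None,
) -> SyntheticCohort:
    """Build a per-condition cohort from a preset with per-animal jitter.

    ``jitter`` is the relative SD of multiplicative log-normal jitter
    applied to amplitude, tau, k1 and k2 per animal.
    """
    if condition not in CONDITION_PRESETS:
        raise KeyError(f"unknown condition preset {condition!r}")
    base = dict(CONDITION_PRESETS[condition])
    base.update(overrides or {})
    # stable across processes (str hash randomization would break determinism)
    tag = zlib.crc32(condition.encode("utf-8"))
    rng = np.random.default_rng(np.random.SeedSequence([seed, tag]))
    specs = []
    for i in range(n_animals):
        factors = np.exp(rng.normal(0.0, jitter, 4))
        specs.append(
            AnimalSpec(
                condition=condition,
                t0=base["t0"],
                amplitude=base["amplitude"] * factors[0],
                alpha=base["alpha"],
                tau=base["tau"] * factors[1],
                k1=base["k1"] * factors[2],
                k2=base["k2"] * factors[3],
                noise_sd=base["noise_sd"],
                seed=i,
                animal_id=f"{condition}-{i:02d}",
            )
        )
    return generate_cohort(specs, times, seed=seed)


def build_shell_phantom(
    outer_thickness: int,
    cube_edge: int,
    i_out: TimeSignalCurve,
    i_in: TimeSignalCurve,
    times=None,
    baseline: float = 100.0,
) -> tuple[Dynamic4D, LabelVolume]:
    """Voxelized cubic phantom whose shell/core carry two planted curves.

    One cubic region of edge ``cube_edge`` sits in a zero background with a
    1-voxel margin.  Its 6-connected erosion of depth ``outer_thickness``
    defines the core; shell voxels carry ``baseline + I_out(t)``, core
    voxels ``baseline + I_in(t)``.  Curves are planted as absolute percent
    offsets on a baseline intensity of 100, so per-voxel normalization
    recovers them exactly.
    """
    if cube_edge <= 2 * outer_thickness:
        raise ValueError(
            f"cube_edge ({cube_edge}) must exceed twice the outer thickness "
            f"({outer_thickness}); the inner core would be empty"
        )
    if times is None:
        times = i_out.times
    times = np.asarray(times, dtype=float)
    if not np.array_equal(i_out.times, i_in.times):
        raise ValueError("outer and inner curves must share one time grid")

    shape = (cube_edge + 2,) * 3
    region = np.zeros(shape, dtype=bool)
    region[1:-1, 1:-1, 1:-1] = True
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connected
    core = ndimage.binary_erosion(
        region, structure=structure, iterations=outer_thickness, border_value=0
    )
    shell = region & ~core

    frames = np.zeros((times.size,) + shape)
    frames[:, region] = baseline
    frames[:, shell] += i_out.values[:, None]
    frames[:, core] += i_in.values[:, None]

    lab = LabelVolume(
        region.astype(np.int16), voxel_size=(1.0, 1.0, 1.0), lookup={1: "phantom"}
    )
    return Dynamic4D(frames, times, baseline_index=0), lab


def synthetic_calcium_trace(
    kind: str,
    duration_s: float,
    rate: float = 2000.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic fluorescence trace mimicking two cortical brain states.

    ``"iso_burst"``: silent periods with slow burst-like phases (< 1 Hz
    envelope), concentrating power below 1 Hz.  ``"med_persistent"``:
    persistent broadband activity with a delta-band (1-4 Hz) emphasis.
    Both are normalized to unit variance so band powers are comparable.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    if kind == "iso_burst":
        # burst envelope at ~0.4 Hz modulating faster activity
        envelope = np.clip(np.sin(2 * np.pi * 0.4 * t), 0.0, None) ** 2
        carrier = rng.normal(0.0, 1.0, n)
        x = envelope * (1.0 + 0.3 * carrier)
    elif kind == "med_persistent":
        x = (
            np.sin(2 * np.pi * 2.5 * t + rng.uniform(0, 2 * np.pi))
            + 0.5 * np.sin(2 * np.pi * 8.0 * t + rng.uniform(0, 2 * np.pi))
            + 0.3 * rng.normal(0.0, 1.0, n)
        )
    else:
        raise ValueError(f"unknown trace kind {kind!r}")
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x
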