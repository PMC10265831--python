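"""Shared primitive types and I/O for the standard formats the pipeline touches.

Images travel as NIfTI (via :mod:`nibabel`), time-signal-curve (TSC) tables
as TSV with columns ``time_min, value_pct, label, condition, animal_id``,
and region lookup tables as two-column TSV (``region_id, region_name``).

Conventions
-----------
* Percent change from baseline: ``100 * (S - BL) / BL``; the baseline frame
  maps to 0 by construction.
* Time origin ``t = 0`` is the pre-contrast baseline scan; all downstream
  integrals use this origin.  Time stamps are minutes, strictly increasing,
  and need not be uniformly spaced.
* Voxel indices are 0-based; all masks live on the atlas grid; no
  resampling is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Dynamic4D",
    "LabelVolume",
    "TimeSignalCurve",
    "extract_region_tsc",
    "normalize_to_baseline",
    "read_label_volume",
    "read_lookup_table",
    "read_tsc_table",
    "write_label_volume",
    "write_tsc_table",
]

TSC_COLUMNS = ("time_min", "value_pct", "label", "condition", "animal_id")


@dataclass
class TimeSignalCurve:
    """A sampled region/compartment signal in percent change from baseline.

    Parameters
    ----------
    times : array-like
        Acquisition times in minutes, strictly increasing, length >= 4.
    values : array-like
        Percent signal change from baseline, same length as ``times``.
    label : str
        Region or compartment identifier.
    condition : str
        Anesthetic-regimen tag.
    animal_id : str
        Subject identifier (empty for aggregate curves).
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    condition: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError(
                f"times ({self.times.size}) and values ({self.values.size}) "
                "must have equal length"
            )
        if self.times.size < 4:
            raise ValueError("a time signal curve needs at least 4 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray, **kwargs) -> "TimeSignalCurve":
        """Return a copy carrying ``values`` on the same time grid."""
        meta = dict(label=self.label, condition=self.condition, animal_id=self.animal_id)
        meta.update(kwargs)
        return TimeSignalCurve(self.times.copy(), np.asarray(values, float), **meta)


@dataclass
class LabelVolume:
    """A 3-D integer atlas label image with voxel sizes and a region lookup.

    Label 0 is background.  Every region id that is queried must exist in
    ``lookup``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lookup: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must hold integer region ids")
        if self.voxels.min() < 0:
            raise ValueError("labels must be nonnegative integers")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def region_name(self, region_id: int) -> str:
        if region_id not in self.lookup:
            raise KeyError(f"region id {region_id} is not in the lookup table")
        return self.lookup[region_id]

    def region_mask(self, region_id: int) -> np.ndarray:
        """Boolean mask of ``region_id``; the id must exist in the lookup."""
        self.region_name(region_id)
        return self.voxels == region_id

    def region_ids(self) -> list[int]:
        ids = np.unique(self.voxels)
        return [int(i) for i in ids if i != 0]


@dataclass
class Dynamic4D:
    """An ordered 4-D dynamic series: frames, frame times and baseline index.

    ``frames`` has shape ``(n_frames, nx, ny, nz)``; ``times`` are frame
    midpoints in minutes, strictly increasing; ``baseline_index`` addresses
    the pre-contrast frame.
    """

    frames: np.ndarray
    times: np.ndarray
    baseline_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a 4-D array (t, x, y, z)")
        if self.times.ndim != 1 or self.times.size != self.frames.shape[0]:
            raise ValueError("times length must equal the number of frames")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not 0 <= self.baseline_index < self.frames.shape[0]:
            raise IndexError("baseline_index addresses no existing frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def normalize_to_baseline(raw, baseline_index: int) -> np.ndarray:
    """Convert raw intensities to percent change from the baseline sample.

    ``value_i = 100 * (raw_i - raw[baseline_index]) / raw[baseline_index]``.

    Raises
    ------
    ValueError
        If the baseline intensity is not strictly positive (the division is
        undefined / unphysical).
    """
    raw = np.asarray(raw, dtype=float)
    baseline = raw[baseline_index]
    if not baseline > 0:
        raise ValueError(
            f"baseline intensity must be positive, got {baseline!r}"
        )
    return 100.0 * (raw - baseline) / baseline


def extract_region_tsc(
    dyn: Dynamic4D, lab: LabelVolume, region_id: int, condition: str = "", animal_id: str = ""
) -> TimeSignalCurve:
    """Mean-intensity TSC of one atlas region, normalized to baseline.

    Per frame, the mean raw intensity over the region's voxels is taken and
    the resulting series is normalized to percent change from the baseline
    frame.
    """
    mask = lab.region_mask(region_id)
    if not mask.any():
        raise ValueError(
            f"region {region_id} ({lab.lookup.get(region_id, '?')}) has no voxels"
        )
    if mask.shape != dyn.frames.shape[1:]:
        raise ValueError("label volume and dynamic frames have different shapes")
    raw = dyn.frames[:, mask].mean(axis=1)
    values = normalize_to_baseline(raw, dyn.baseline_index)
    return TimeSignalCurve(
        dyn.times, values, label=lab.region_name(region_id),
        condition=condition, animal_id=animal_id,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_label_volume(path, lookup_path=None) -> LabelVolume:
    """Read a NIfTI label image (and optional TSV lookup) as a LabelVolume."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: label volume has non-integer voxel values")
        data = rounded.astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    lookup = read_lookup_table(lookup_path) if lookup_path is not None else {}
    return LabelVolume(data, voxel_size=voxel_size, lookup=lookup)


def write_label_volume(lab: LabelVolume, path) -> None:
    affine = np.diag(list(lab.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(lab.voxels.astype(np.int32), affine), str(path))


def read_lookup_table(path) -> dict[int, str]:
    """Read a two-column TSV ``region_id <TAB> region_name`` lookup table."""
    table = pd.read_csv(path, sep="\t")
    cols = list(table.columns[:2])
    return {int(r): str(n) for r, n in zip(table[cols[0]], table[cols[1]])}


def read_dynamic(path, times, baseline_index: int = 0) -> Dynamic4D:
    """Read a 4-D NIfTI series; frame times must be supplied externally."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got {data.ndim}-D")
    # NIfTI stores time last; internal layout is (t, x, y, z)
    frames = np.moveaxis(data, -1, 0)
    return Dynamic4D(frames, np.asarray(times, float), baseline_index)


def write_dynamic(dyn: Dynamic4D, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    data = np.moveaxis(dyn.frames, 0, -1)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# TSC table I/O


def write_tsc_table(curves, path) -> None:
    """Write curves to a TSV table, one row per (curve, time point)."""
    rows = []
    for c in curves:
        for t, v in zip(c.times, c.values):
            rows.append((t, v, c.label, c.condition, c.animal_id))
    frame = pd.DataFrame(rows, columns=list(TSC_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_tsc_table(path) -> list[TimeSignalCurve]:
    """Read a TSC TSV table back into a list of curves.

    Rows are grouped by (animal_id, label, condition); each group becomes
    one curve sorted by time.
    """
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(TSC_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing TSC columns {sorted(missing)}")
    curves = []
    for (animal, label, condition), grp in frame.groupby(
        ["animal_id", "label", "condition"], sort=True
    ):
        grp = grp.sort_values("time_min")
        curves.append(
            TimeSignalCurve(
                grp["time_min"].to_numpy(float),
                grp["value_pct"].to_numpy(float),
                label=str(label),
                condition=str(condition),
                animal_id=str(animal),
            )
        )
    return curves


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
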