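"""Shell-mask compartment geometry.

A labeled brain region is split into a closed outer envelope of uniform
voxel thickness ``s`` (the region minus its ``s``-fold morphological
erosion) and the enclosed inner compartment (the erosion itself).  The
structuring element is 6-connected (face neighbors) by default, which
yields uniform thickness in voxels along the axes; 18/26-connectivity is a
config switch.  Out-of-volume voxels count as background, so region
surfaces touching the image border still peel.

Compartment curves aggregate per-voxel percent-change signals by *summing*
over each mask (the model operates on summed signals; region-level TSCs
use means — a flag selects the mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from glymkin.io_core import Dynamic4D, LabelVolume, TimeSignalCurve, normalize_to_baseline

__all__ = ["CompartmentPair", "compartment_curves", "split_region"]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class CompartmentPair:
    """Outer/inner masks at shell thickness ``s`` with aggregated curves."""

    region_id: int
    s: int
    outer_mask: np.ndarray
    inner_mask: np.ndarray
    n_outer: int
    n_inner: int
    i_out: TimeSignalCurve | None = None
    i_in: TimeSignalCurve | None = None
    usable: bool = True
    message: str = ""


def split_region(
    lab: LabelVolume, region_id: int, s: int, connectivity: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Split a region into (outer envelope, inner core) masks at thickness ``s``.

    The inner mask is the region mask eroded ``s`` times with the chosen
    structuring element; the outer mask is the set difference.  The two are
    disjoint and their union is the region.  The inner mask may be empty
    when erosion exhausts the region.
    """
    if s < 1:
        raise ValueError("shell thickness s must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    region = lab.region_mask(region_id)
    if not region.any():
        raise ValueError(f"region {region_id} is empty")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    inner = ndimage.binary_erosion(
        region, structure=structure, iterations=s, border_value=0
    )
    outer = region & ~inner
    return outer, inner


def compartment_curves(
    dyn: Dynamic4D,
    outer_mask: np.ndarray,
    inner_mask: np.ndarray,
    region_id: int = 0,
    s: int = 0,
    aggregate: str = "sum",
    **meta,
) -> CompartmentPair:
    """Aggregate normalized voxel signals over the outer and inner masks.

    Each voxel is normalized to percent change from its own baseline-frame
    intensity, then aggregated per frame (``aggregate="sum"`` by default,
    ``"mean"`` optionally).  An empty inner mask yields a degenerate,
    unusable pair rather than an error.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    if not outer_mask.any():
        raise ValueError("outer mask is empty")
    n_outer = int(outer_mask.sum())
    n_inner = int(inner_mask.sum())
    i_out = _aggregate_mask(dyn, outer_mask, aggregate, label="outer", **meta)
    pair = CompartmentPair(
        region_id=region_id, s=s,
        outer_mask=outer_mask, inner_mask=inner_mask,
        n_outer=n_outer, n_inner=n_inner, i_out=i_out,
    )
    if n_inner == 0:
        pair.usable = False
        pair.message = f"inner compartment is empty at thickness s={s}"
        return pair
    pair.i_in = _aggregate_mask(dyn, inner_mask, aggregate, label="inner", **meta)
    return pair


def _aggregate_mask(dyn: Dynamic4D, mask: np.ndarray, aggregate: str, **meta) -> TimeSignalCurve:
    vox = dyn.frames[:, mask]  # (n_frames, n_voxels)
    baseline = vox[dyn.baseline_index]
    if np.any(baseline <= 0):
        raise ValueError("nonpositive baseline intensity inside the mask")
    pct = 100.0 * (vox - baseline) / baseline
    values = pct.sum(axis=1) if aggregate == "sum" else pct.mean(axis=1)
    return TimeSignalCurve(dyn.times, values, **meta)
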