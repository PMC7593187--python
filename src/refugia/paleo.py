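"""Paleoclimate hindcasting and the climate-stability (refugium) surface.

Millennial-scale climate is supplied as coarse anomaly grids (paleo minus
modern, in each variable's units) per time slice, following the delta /
change-factor convention of paleoclimate simulators: the coarse anomaly is
interpolated bilinearly to the fine baseline grid and added to the modern
field, so fine-scale topographic structure is preserved while the slice
carries the large-scale climate signal.  Suitability is projected for each
slice, clipped to zero under the slice's ice sheet, and the per-cell sum
over all slices plus the present defines long-term climate stability;
cells in the top fraction (default 30%) of sums are flagged as putative
glacial refugia.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .rasters import CoarseGrid, Raster, SuitabilityMap, VARIABLES
from .sdm import EnsembleModel, extract_features, predict_ensemble

__all__ = [
    "TimeSlice",
    "TimeSliceSet",
    "StabilityMap",
    "downscale_delta",
    "project_timeslices",
    "stability_surface",
]

N_SLICES = 21  # every 1,000 years from the LGM (21 ka) to 1 ka before present


@dataclass(frozen=True)
class TimeSlice:
    """One millennial slice: age, coarse anomalies per variable, ice mask."""

    age_ka: int
    anomalies: Mapping[str, Raster]
    ice: Raster  # coarse {0,1} grid; 1 = under the ice sheet


@dataclass(frozen=True)
class TimeSliceSet:
    """Ordered paleo slices (oldest first) plus the modern fine baseline."""

    slices: tuple[TimeSlice, ...]
    baseline: Mapping[str, Raster]

    def __post_init__(self) -> None:
        ages = [s.age_ka for s in self.slices]
        if any(nxt >= prev for prev, nxt in zip(ages, ages[1:])):
            raise ValueError("slice ages must strictly decrease toward present")


def downscale_delta(
    anomaly: Raster, baseline: Raster, floor_zero: bool = False
) -> Raster:
    """Change-factor downscaling: bilinear anomaly interpolation + baseline.

    Temperature anomalies are purely additive; precipitation uses
    ``floor_zero=True`` so the result never goes negative.  Fine cells
    outside the span of coarse cell centers get nearest-edge extrapolation
    (with a warning), which is exact for spatially uniform anomalies.
    """
    ys = anomaly.y_centers()[::-1]  # ascending for the interpolator
    xs = anomaly.x_centers()
    grid_vals = anomaly.values[::-1, :]
    interp = RegularGridInterpolator(
        (ys, xs), grid_vals, method="linear", bounds_error=False
    )
    fy = baseline.y_centers()
    fx = baseline.x_centers()
    if fy.max() > ys.max() or fy.min() < ys.min() or fx.max() > xs.max() or fx.min() < xs.min():
        warnings.warn("fine cells outside coarse coverage; nearest-edge extrapolation")
    yy = np.clip(fy, ys.min(), ys.max())
    xx = np.clip(fx, xs.min(), xs.max())
    pts = np.stack(np.meshgrid(yy, xx, indexing="ij"), axis=-1).reshape(-1, 2)
    delta = interp(pts).reshape(baseline.shape)
    out = baseline.values + delta
    if floor_zero:
        out = np.maximum(out, 0.0)
    return baseline.with_values(out)


def _apply_ice(probs: np.ndarray, ice: Raster) -> tuple[np.ndarray, np.ndarray]:
    mask = np.nan_to_num(ice.values.ravel()) >= 0.5
    out = probs.copy()
    out[mask & ~np.isnan(out)] = 0.0
    return out, mask


def project_timeslices(
    model: EnsembleModel,
    slices: TimeSliceSet,
    grid: CoarseGrid,
) -> list[SuitabilityMap]:
    """Suitability maps for every paleo slice plus the present day.

    For each slice the four variables are downscaled, extreme-cell
    features extracted and the gated ensemble evaluated; cells under the
    slice's ice sheet are clipped to probability zero.  Returns maps
    ordered oldest to youngest with the present-day map appended last.
    """
    maps: list[SuitabilityMap] = []
    for sl in slices.slices:
        layers = {}
        for v in VARIABLES:
            floor = v.startswith("p_")
            layers[v] = downscale_delta(
                sl.anomalies[v], slices.baseline[v], floor_zero=floor
            )
        feats = extract_features(layers, grid)
        m = predict_ensemble(model, feats, tag=f"{sl.age_ka}ka")
        probs, ice_mask = _apply_ice(m.probs, sl.ice)
        maps.append(SuitabilityMap(probs=probs, tag=m.tag, ice=ice_mask))
    present = predict_ensemble(
        model, extract_features(dict(slices.baseline), grid), tag="present"
    )
    maps.append(present)
    return maps


@dataclass(frozen=True)
class StabilityMap:
    """Summed suitability over time with top-fraction refugium flags.

    ``sums`` is flat per cell (NaN where masked); ``rank`` is 1-based by
    descending sum with ties broken by ascending cell id; ``flag`` marks
    the refugium cells.
    """

    sums: np.ndarray
    rank: np.ndarray
    flag: np.ndarray
    top_frac: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.sums.size),
                "sum": self.sums,
                "rank": self.rank,
                "flag": self.flag.astype(int),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def stability_surface(
    maps: Sequence[SuitabilityMap],
    top_frac: float = 0.30,
    include_ties: bool = False,
) -> StabilityMap:
    """Sum suitability over slices and flag the most stable cells.

    Exactly ``ceil(top_frac * n_unmasked)`` cells are flagged (cells tied
    at the cut are broken deterministically by ascending cell id, unless
    ``include_ties`` extends the flag to every tied cell).  Ice-clipped
    cells contribute zero to the sum; cells masked in any map are excluded
    from the ranking.
    """
    if not maps:
        raise ValueError("empty map list")
    n = maps[0].n_cells
    if any(m.n_cells != n for m in maps):
        raise ValueError("maps do not share geometry")
    stack = np.stack([m.probs for m in maps])
    masked = np.isnan(stack).any(axis=0)
    sums = stack.sum(axis=0)
    sums[masked] = np.nan
    unmasked_ids = np.flatnonzero(~masked)
    k = math.ceil(top_frac * unmasked_ids.size)
    # sort by (-sum, cell_id): stable, deterministic tie rule
    order = unmasked_ids[np.lexsort((unmasked_ids, -sums[unmasked_ids]))]
    rank = np.zeros(n, dtype=int)
    rank[order] = np.arange(1, order.size + 1)
    flag = np.zeros(n, dtype=bool)
    flag[order[:k]] = True
    if include_ties and k and k < order.size:
        cut = sums[order[k - 1]]
        flag[order[sums[order] == cut]] = True
    return StabilityMap(sums=sums, rank=rank, flag=flag, top_frac=top_frac)
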