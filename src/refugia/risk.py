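"""Future-scenario risk analysis: range change and haplotypes at risk.

Ensemble probabilities are binarized at a presence/absence threshold —
either a fixed study value or the "range-edge" rule, where the threshold
is the modeled probability of the occupied cell with the lowest mean
elevation (the species' low-elevation climatic range edge).  Currently
occupied cells then either persist or go extinct under a future scenario;
unoccupied cells that become suitable are colonization candidates,
reported but not netted against losses.  A mountain region whose occupied
cells are all lost takes its region-unique haplotypes with it; the
haplotype-risk statistic Hr sums those unique haplotypes over lost
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import HaplotypeTable
from .rasters import CoarseGrid, SuitabilityMap

__all__ = [
    "ThresholdSpec",
    "derive_threshold",
    "CellFates",
    "classify_cells",
    "range_change",
    "HaplotypeRisk",
    "haplotype_risk",
    "haplotypes_at_risk",
    "elevation_trend",
]

STUDY_THRESHOLD = 0.49  # range-edge probability of the lowest-elevation occupied cell


@dataclass(frozen=True)
class ThresholdSpec:
    """How to binarize suitability: a fixed value or the range-edge rule."""

    mode: str = "fixed"  # {"fixed", "range-edge"}
    value: float = STUDY_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "range-edge"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed" and not (0 < self.value < 1):
            raise ValueError("fixed threshold must lie in (0, 1)")


def derive_threshold(
    current: SuitabilityMap, grid: CoarseGrid, spec: ThresholdSpec
) -> float:
    """Resolve the presence/absence threshold for one current map."""
    if spec.mode == "fixed":
        return spec.value
    occ = grid.presence_ids()
    if occ.size == 0:
        raise ValueError("no occupied cells to derive a range-edge threshold")
    elev = grid.elevation.ravel()[occ]
    edge = occ[int(np.argmin(elev))]
    t = float(current.probs[edge])
    if np.isnan(t):
        raise ValueError("range-edge cell is masked in the current map")
    return t


@dataclass(frozen=True)
class CellFates:
    """Per-cell fate under one scenario.

    ``fate`` holds one of ``persistence``/``extinction``/``colonization``/
    ``absent`` per flat cell id.
    """

    fate: np.ndarray
    scenario: str
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.fate.size),
                "scenario": self.scenario,
                "class": self.fate,
            }
        )


def classify_cells(
    current: SuitabilityMap,
    future: SuitabilityMap,
    grid: CoarseGrid,
    threshold: float,
    scenario: str = "future",
) -> CellFates:
    """Classify every coarse cell by occupancy now and suitability later.

    A cell is suitable iff probability >= threshold (the boundary counts
    as suitable, so the range-edge cell itself is suitable at present).
    """
    if current.n_cells != future.n_cells or current.n_cells != grid.n_cells:
        raise ValueError("maps and grid do not share geometry")
    occ = grid.presence.ravel()
    suit = np.nan_to_num(future.probs, nan=-np.inf) >= threshold
    fate = np.where(
        occ,
        np.where(suit, "persistence", "extinction"),
        np.where(suit, "colonization", "absent"),
    ).astype(object)
    return CellFates(fate=fate, scenario=scenario, threshold=threshold)


def range_change(
    fates: CellFates,
    grid: CoarseGrid,
    region_alias: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-region occupancy loss under one scenario.

    Percent range change counts only currently occupied cells,
    ``100 * (n_persisting - n_occupied) / n_occupied`` (colonization is
    tallied separately, never netted); a region is lost when every
    occupied cell goes extinct.  ``region_alias`` pools labels (e.g. three
    Alps subranges into one Alps block) before tallying.
    """
    alias = dict(region_alias or {})
    region = np.array(
        [alias.get(r, r) if r is not None else None for r in grid.region_id.ravel()],
        dtype=object,
    )
    occ = grid.presence.ravel()
    unassigned = occ & (region == None)  # noqa: E711
    if unassigned.any():
        raise ValueError(
            f"{int(unassigned.sum())} occupied cells have no region label"
        )
    rows = []
    for r in dict.fromkeys(region[occ]):
        in_r = region == r
        n_occ = int((in_r & occ).sum())
        if n_occ == 0:
            warnings.warn(f"region {r!r} has no occupied cells; excluded")
            continue
        n_persist = int((in_r & occ & (fates.fate == "persistence")).sum())
        n_colon = int((in_r & (fates.fate == "colonization")).sum())
        rows.append(
            {
                "region": r,
                "n_occupied": n_occ,
                "n_persisting": n_persist,
                "n_colonization": n_colon,
                "range_change_pct": 100.0 * (n_persist - n_occ) / n_occ,
                "region_lost": n_persist == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HaplotypeRisk:
    """Haplotype-risk summary for one scenario."""

    scenario: str
    hr: int
    lost_regions: tuple[str, ...]
    at_risk_haplotypes: tuple[int, ...]


def haplotype_risk(
    region_lost: Mapping[str, bool],
    hu: Mapping[str, int],
    table: HaplotypeTable | None = None,
    scenario: str = "future",
) -> HaplotypeRisk:
    """Hr = sum of region-unique haplotype counts over fully lost regions.

    ``region_lost`` maps every spatially modeled region to whether all its
    occupied cells are projected unsuitable; ``hu`` maps genetically
    sampled regions to their unique-haplotype counts.  Every genetic
    region must appear in the spatial layer.  When a
    :class:`~refugia.popgen.HaplotypeTable` is given the at-risk haplotype
    ids themselves are listed.
    """
    missing = sorted(set(hu) - set(region_lost))
    if missing:
        raise ValueError(
            f"regions in genetics but absent from spatial layer: {missing}"
        )
    lost = tuple(r for r in hu if region_lost[r])
    hr = int(sum(hu[r] for r in lost))
    at_risk: tuple[int, ...] = ()
    if table is not None:
        at_risk = tuple(h for r in lost for h in table.unique_to(r))
    return HaplotypeRisk(scenario, hr, lost, at_risk)


def haplotypes_at_risk(
    report: pd.DataFrame,
    diversity: pd.DataFrame,
    table: HaplotypeTable | None = None,
    scenario: str = "future",
) -> HaplotypeRisk:
    """Join a :func:`range_change` report with a regional diversity table.

    ``diversity`` needs ``region`` and ``Hu`` columns (the 'All' row, if
    present, is ignored).
    """
    lost = dict(zip(report["region"], report["region_lost"]))
    div = diversity[diversity["region"] != "All"]
    hu = dict(zip(div["region"], div["Hu"].astype(int)))
    return haplotype_risk(lost, hu, table=table, scenario=scenario)


def elevation_trend(
    delta_p: Sequence[float], elevation: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of suitability change on cell mean elevation.

    Returns ``(slope, r2, F, p)`` with the F statistic on (1, n-2)
    degrees of freedom and a two-sided p-value; a positive slope means
    high-elevation cells lose less suitability.
    """
    y = np.asarray(delta_p, dtype=float)
    x = np.asarray(elevation, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("constant elevation")
    if np.ptp(y) == 0:  # flat response: zero slope, no explained variance
        return 0.0, 0.0, 0.0, 1.0
    fit = stats.linregress(x, y)
    n = x.size
    r2 = fit.rvalue**2
    if r2 >= 1.0:
        f = np.inf
    else:
        f = r2 / (1 - r2) * (n - 2)
    return float(fit.slope), float(r2), float(f), float(fit.pvalue)
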