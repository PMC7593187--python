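"""Synthetic study systems with known ground truth.

Generates everything the pipeline consumes — a planar mountain landscape
with fine seasonal climate rasters, a coarse occupancy lattice partitioned
into 13 labeled mountain regions, a millennial warming trajectory from the
LGM with ice masks, two future warming scenarios, and a regional COI
alignment with planted haplotype structure — so every downstream stage can
be checked against the generator's own truth without any external data.

The default world mirrors the shape of the empirical system it emulates:
13 mountain regions, 215 sequences of 649 bp collapsing to 31 haplotypes
of which 27 are region-unique, a 50-km occupancy lattice over ~4.5-km
climate cells (here: 20x20 coarse cells of 50 km, each owning a 10x10
block of 5-km fine cells), 21 millennial time slices plus the present, and
low/high future scenarios of roughly +1 and +2.5 deg C.

Geometry is planar (km); occurrence truth is a logistic in the eight
extreme-cell climate features, by default driven by the minimum warm-
quarter temperature of a cell (a cold-adapted species tracks cool summer
microclimate at high elevation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .popgen import Alignment
from .rasters import CoarseGrid, Raster, SuitabilityMap, VARIABLES
from .paleo import TimeSlice, TimeSliceSet, N_SLICES
from .sdm import FEATURE_COLUMNS, extract_features

__all__ = [
    "MassifSpec",
    "HaplotypeSpec",
    "WorldSpec",
    "Landscape",
    "World",
    "make_landscape",
    "make_occupancy",
    "make_timeseries",
    "make_sequences",
    "make_future",
    "true_suitability",
    "true_map",
    "true_ensemble",
    "planted_warming_offset",
    "make_world",
    "write_world",
]


@dataclass(frozen=True)
class MassifSpec:
    """One mountain block: a Gaussian elevation bump plus its region label."""

    name: str
    row: float  # coarse-cell units, 0 = northernmost row
    col: float
    peak_m: float
    sigma_km: float = 45.0
    label_radius_km: float = 125.0


@dataclass(frozen=True)
class HaplotypeSpec:
    """A planted haplotype: substitutions from the root and regional copies."""

    key: str
    n_mut: int
    copies: Mapping[str, int]


DEFAULT_MASSIFS = (
    MassifSpec("scotland", 2.0, 5.0, 1300.0),
    MassifSpec("england", 4.5, 4.0, 1000.0),
    MassifSpec("vosges", 7.0, 9.0, 1400.0),
    MassifSpec("tatras", 6.5, 14.0, 2300.0),
    MassifSpec("carpathians", 8.5, 16.5, 2400.0),
    MassifSpec("massif_central", 11.0, 6.0, 1800.0),
    MassifSpec("alps_west", 11.0, 10.0, 3500.0),
    MassifSpec("alps_central", 10.5, 12.5, 3300.0),
    MassifSpec("alps_east", 10.0, 15.0, 3000.0),
    MassifSpec("balkans_west", 13.0, 16.0, 2500.0),
    MassifSpec("apennines", 14.5, 11.0, 1950.0),
    MassifSpec("pyrenees", 15.0, 5.5, 3000.0),
    MassifSpec("cantabrians", 15.5, 2.5, 2300.0),
)

# 31 planted haplotypes: 4 shared across regions (the widespread central
# haplotype s1 is the root itself), 27 confined to a single region.
DEFAULT_HAPLOTYPES = (
    HaplotypeSpec(
        "s1", 0, {"vosges": 5, "scotland": 30, "england": 20, "alps_west": 6}
    ),
    HaplotypeSpec("s2", 2, {"scotland": 6, "apennines": 8, "cantabrians": 4}),
    HaplotypeSpec("s3", 3, {"massif_central": 5, "pyrenees": 8, "cantabrians": 6}),
    HaplotypeSpec(
        "s4", 1, {"alps_west": 4, "alps_east": 8, "alps_central": 9, "balkans_west": 3}
    ),
    HaplotypeSpec("scotland_u1", 1, {"scotland": 4}),
    HaplotypeSpec("england_u1", 1, {"england": 15}),
    HaplotypeSpec("england_u2", 1, {"england": 4}),
    HaplotypeSpec("england_u3", 2, {"england": 2}),
    HaplotypeSpec("england_u4", 2, {"england": 2}),
    HaplotypeSpec("england_u5", 3, {"england": 1}),
    HaplotypeSpec("england_u6", 3, {"england": 1}),
    HaplotypeSpec("pyrenees_u1", 4, {"pyrenees": 6}),
    HaplotypeSpec("pyrenees_u2", 4, {"pyrenees": 3}),
    HaplotypeSpec("pyrenees_u3", 5, {"pyrenees": 2}),
    HaplotypeSpec("pyrenees_u4", 2, {"pyrenees": 1}),
    HaplotypeSpec("massif_central_u1", 4, {"massif_central": 3}),
    HaplotypeSpec("carpathians_u1", 6, {"carpathians": 6}),
    HaplotypeSpec("carpathians_u2", 7, {"carpathians": 4}),
    HaplotypeSpec("tatras_u1", 3, {"tatras": 7}),
    HaplotypeSpec("tatras_u2", 4, {"tatras": 3}),
    HaplotypeSpec("balkans_west_u1", 2, {"balkans_west": 5}),
    HaplotypeSpec("balkans_west_u2", 2, {"balkans_west": 3}),
    HaplotypeSpec("balkans_west_u3", 3, {"balkans_west": 1}),
    HaplotypeSpec("apennines_u1", 3, {"apennines": 2}),
    HaplotypeSpec("alps_west_u1", 1, {"alps_west": 8}),
    HaplotypeSpec("alps_west_u2", 1, {"alps_west": 3}),
    HaplotypeSpec("alps_west_u3", 2, {"alps_west": 2}),
    HaplotypeSpec("alps_west_u4", 2, {"alps_west": 1}),
    HaplotypeSpec("alps_west_u5", 3, {"alps_west": 1}),
    HaplotypeSpec("alps_east_u1", 2, {"alps_east": 2}),
    HaplotypeSpec("alps_central_u1", 2, {"alps_central": 1}),
)


@dataclass(frozen=True)
class WorldSpec:
    """Full parameterization of a synthetic world; one seed fixes all draws."""

    coarse_shape: tuple[int, int] = (20, 20)
    factor: int = 10
    coarse_cellsize: float = 50.0  # km
    base_elevation_m: float = 100.0
    massifs: tuple[MassifSpec, ...] = DEFAULT_MASSIFS
    lapse_rate: float = -6.5  # deg C per km of elevation
    t_warm_sea: float = 24.0  # warm-quarter sea-level temperature, south edge
    t_cold_sea: float = 8.0
    meridional_gradient_warm: float = -0.006  # deg C per km northward
    meridional_gradient_cold: float = -0.008
    temp_noise_sd: float = 0.3  # deg C, spatially smooth
    precip_noise_sd: float = 8.0  # mm
    noise_smooth_cells: float = 6.0
    p_cold_base: float = 180.0  # mm
    p_warm_base: float = 220.0
    orography_gain_cold: float = 0.10  # mm per m of elevation
    orography_gain_warm: float = 0.08
    true_intercept: float = 16.2
    true_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"t_warm_min": -1.2}
    )
    occupancy_threshold: float = 0.5
    lgm_offset: float = -4.5  # deg C at 21 ka
    final_offset: float = -0.2  # deg C at 1 ka
    precip_per_degree: float = 8.0  # mm of precipitation anomaly per deg C
    ice_cutoff: float = -20.0  # coldest-cell cold-quarter T below this: ice
    scenarios: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (1.0, -5.0), "high": (2.5, -15.0)}
    )
    sequence_length: int = 649
    haplotypes: tuple[HaplotypeSpec, ...] = DEFAULT_HAPLOTYPES
    region_stem_mut: int = 5  # substitutions shared by a region's unique haplotypes
    seed: int = 1717


@dataclass
class Landscape:
    elevation: Raster
    climate: dict[str, Raster]
    grid: CoarseGrid


def _smooth_noise(rng, shape, sd, smooth) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    w = gaussian_filter(rng.standard_normal(shape), smooth)
    return w * (sd / w.std())


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_landscape(spec: WorldSpec) -> Landscape:
    """Elevation, four fine climate rasters and the labeled coarse grid."""
    nrows, ncols = spec.coarse_shape
    if nrows <= 0 or ncols <= 0 or spec.factor <= 0:
        raise ValueError("grid dimensions must be positive")
    f = spec.factor
    fine_cs = spec.coarse_cellsize / f
    fr, fc = nrows * f, ncols * f
    x = (np.arange(fc) + 0.5) * fine_cs
    y = (fr - np.arange(fr) - 0.5) * fine_cs  # row 0 north
    xx, yy = np.meshgrid(x, y)
    elev = np.full((fr, fc), spec.base_elevation_m)
    height_km = nrows * spec.coarse_cellsize
    centers = {}
    for m in spec.massifs:
        cx = (m.col + 0.5) * spec.coarse_cellsize
        cy = height_km - (m.row + 0.5) * spec.coarse_cellsize
        centers[m.name] = (cx, cy)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        elev = elev + m.peak_m * np.exp(-d2 / (2 * m.sigma_km**2))
    rng_tw, rng_tc, rng_pc, rng_pw = _child_rngs(spec.seed, 4)
    ekm = elev / 1000.0
    t_warm = (
        spec.t_warm_sea
        + spec.meridional_gradient_warm * yy
        + spec.lapse_rate * ekm
        + _smooth_noise(rng_tw, elev.shape, spec.temp_noise_sd, spec.noise_smooth_cells)
    )
    t_cold = (
        spec.t_cold_sea
        + spec.meridional_gradient_cold * yy
        + spec.lapse_rate * ekm
        + _smooth_noise(rng_tc, elev.shape, spec.temp_noise_sd, spec.noise_smooth_cells)
    )
    p_cold = np.maximum(
        spec.p_cold_base
        + spec.orography_gain_cold * elev
        + _smooth_noise(rng_pc, elev.shape, spec.precip_noise_sd, spec.noise_smooth_cells),
        0.0,
    )
    p_warm = np.maximum(
        spec.p_warm_base
        + spec.orography_gain_warm * elev
        + _smooth_noise(rng_pw, elev.shape, spec.precip_noise_sd, spec.noise_smooth_cells),
        0.0,
    )
    climate = {
        "t_cold": Raster(t_cold, fine_cs),
        "t_warm": Raster(t_warm, fine_cs),
        "p_cold": Raster(p_cold, fine_cs),
        "p_warm": Raster(p_warm, fine_cs),
    }
    # coarse grid: block-mean elevation, nearest-massif region labels
    coarse_elev = elev.reshape(nrows, f, ncols, f).mean(axis=(1, 3))
    region = np.full((nrows, ncols), None, dtype=object)
    ccx = (np.arange(ncols) + 0.5) * spec.coarse_cellsize
    ccy = height_km - (np.arange(nrows) + 0.5) * spec.coarse_cellsize
    gx, gy = np.meshgrid(ccx, ccy)
    dist = np.full((nrows, ncols), np.inf)
    for m in spec.massifs:
        cx, cy = centers[m.name]
        d = np.hypot(gx - cx, gy - cy)
        take = (d <= m.label_radius_km) & (d < dist)
        region[take] = m.name
        dist = np.where(take, d, dist)
    grid = CoarseGrid(
        nrows=nrows,
        ncols=ncols,
        cellsize=spec.coarse_cellsize,
        factor=f,
        presence=np.zeros((nrows, ncols), dtype=bool),
        region_id=region,
        elevation=coarse_elev,
    )
    return Landscape(
        elevation=Raster(elev, fine_cs), climate=climate, grid=grid
    )


def true_suitability(features, spec: WorldSpec) -> np.ndarray:
    """The generating model's occurrence probability per coarse cell."""
    logit = np.full(len(features), spec.true_intercept, dtype=float)
    for col, b in spec.true_coefs.items():
        if col not in features.columns:
            raise ValueError(f"unknown feature {col!r} in true model")
        logit = logit + b * features[col].to_numpy(dtype=float)
    return 1.0 / (1.0 + np.exp(-logit))


def true_map(features, spec: WorldSpec, tag: str = "truth") -> SuitabilityMap:
    return SuitabilityMap(probs=true_suitability(features, spec), tag=tag)


class _TrueLogistic:
    """predict_proba adapter around the generating logistic model."""

    def __init__(self, spec: WorldSpec):
        self.intercept = spec.true_intercept
        self.coefs = np.array([spec.true_coefs.get(c, 0.0) for c in FEATURE_COLUMNS])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-(self.intercept + X @ self.coefs)))
        return np.c_[1 - p, p]


def true_ensemble(spec: WorldSpec) -> "EnsembleModel":
    """The generating model wrapped as a single-member ensemble.

    Lets the generator's own truth be pushed through the projection and
    risk machinery, where it serves as an exact oracle.
    """
    from .sdm import EnsembleMember, EnsembleModel

    member = EnsembleMember("truth", _TrueLogistic(spec), 1.0, True)
    return EnsembleModel(
        members=[member],
        inclusion_threshold=0.0,
        split_fraction=1.0,
        seed=spec.seed,
        feature_columns=FEATURE_COLUMNS,
    )


def make_occupancy(
    landscape: Landscape, spec: WorldSpec
) -> tuple[CoarseGrid, np.ndarray]:
    """Presence flags from the true model; returns (grid, true probabilities)."""
    feats = extract_features(landscape.climate, landscape.grid)
    probs = true_suitability(feats, spec)
    presence = np.nan_to_num(probs) >= spec.occupancy_threshold
    if not presence.any():
        raise ValueError("world uninhabitable, adjust spec")
    g = landscape.grid
    grid = CoarseGrid(
        nrows=g.nrows,
        ncols=g.ncols,
        cellsize=g.cellsize,
        factor=g.factor,
        presence=presence.reshape(g.nrows, g.ncols),
        region_id=g.region_id,
        elevation=g.elevation,
        valid=g.valid,
    )
    return grid, probs


def trajectory(spec: WorldSpec) -> np.ndarray:
    """21 millennial temperature offsets, LGM coldest, warming to present."""
    return np.linspace(spec.lgm_offset, spec.final_offset, N_SLICES)


def make_timeseries(
    spec: WorldSpec, landscape: Landscape, offsets: np.ndarray | None = None
) -> TimeSliceSet:
    """Coarse anomaly grids and ice masks for 21 slices (21 ka ... 1 ka).

    Anomalies are spatially uniform per slice (temperature offset plus a
    proportional precipitation anomaly) on a coarse 200-km lattice; the
    ice mask flags coarse cells whose coldest fine cell drops below the
    ice cutoff in that slice.
    """
    offs = trajectory(spec) if offsets is None else np.asarray(offsets, dtype=float)
    if offs.size != N_SLICES:
        raise ValueError(f"trajectory must have {N_SLICES} offsets")
    nrows, ncols = spec.coarse_shape
    f = spec.factor
    # anomaly lattice overhangs the domain so bilinear coverage is complete
    anom_cs = 4 * spec.coarse_cellsize
    height = nrows * spec.coarse_cellsize
    width = ncols * spec.coarse_cellsize
    a_shape = (
        int(np.ceil(height / anom_cs)) + 1,
        int(np.ceil(width / anom_cs)) + 1,
    )
    a_xll = -anom_cs / 2
    a_yll = -anom_cs / 2
    tc_min = (
        landscape.climate["t_cold"].values.reshape(nrows, f, ncols, f).min(axis=(1, 3))
    )
    slices = []
    for i, off in enumerate(offs):
        age = N_SLICES - i
        p_off = spec.precip_per_degree * off
        anomalies = {
            v: Raster(
                np.full(a_shape, off if v.startswith("t_") else p_off),
                anom_cs,
                xll=a_xll,
                yll=a_yll,
            )
            for v in VARIABLES
        }
        ice = Raster(
            ((tc_min + off) < spec.ice_cutoff).astype(float), spec.coarse_cellsize
        )
        slices.append(TimeSlice(age_ka=age, anomalies=anomalies, ice=ice))
    return TimeSliceSet(slices=tuple(slices), baseline=dict(landscape.climate))


def make_future(
    spec: WorldSpec, landscape: Landscape, scenario: str
) -> dict[str, Raster]:
    """Fine climate rasters for a future scenario (uniform warming + drying)."""
    if scenario not in spec.scenarios:
        raise ValueError(f"unknown scenario {scenario!r}")
    dt, dp = spec.scenarios[scenario]
    out = {}
    for v in VARIABLES:
        r = landscape.climate[v]
        if v.startswith("t_"):
            out[v] = r.with_values(r.values + dt)
        else:
            out[v] = r.with_values(np.maximum(r.values + dp, 0.0))
    return out


def make_sequences(spec: WorldSpec) -> tuple[Alignment, dict]:
    """Regional COI alignment with planted haplotype structure.

    The root sequence is uniform over {A,C,G,T}.  Region-unique haplotypes
    share ``region_stem_mut`` substitutions private to their region (a
    regional clade, which is what produces strong among-region AMOVA
    structure) plus ``n_mut`` haplotype-private substitutions; shared
    haplotypes carry only their ``n_mut`` private substitutions.  One site
    per haplotype is reserved so distinct specs are guaranteed distinct
    sequences (only one shared haplotype may equal the root); stem sites
    occupy a disjoint per-region block, so the planted Hamming distance
    from the root is exactly ``n_mut`` (+ the stem size for uniques).
    Returns the alignment plus a truth dict with the planted counts.
    """
    L = spec.sequence_length
    n_haps = len(spec.haplotypes)
    region_order = list(
        dict.fromkeys(r for h in spec.haplotypes for r in h.copies)
    )
    stem = spec.region_stem_mut
    free_start = n_haps + stem * len(region_order)
    if any(h.n_mut + stem > L - free_start for h in spec.haplotypes):
        raise ValueError("mutation count exceeds sequence length")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(5)[4])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    root = rng.choice(bases, size=L)

    def substitute(seq: np.ndarray, sites: np.ndarray, r: np.random.Generator):
        for s in sites:
            others = bases[bases != seq[s]]
            seq[s] = r.choice(others)

    # one stem variant per region, drawn once so regional uniques share it
    stems: dict[str, np.ndarray] = {}
    for k, region in enumerate(region_order):
        variant = root.copy()
        if stem > 0:
            substitute(variant, np.arange(n_haps + k * stem, n_haps + (k + 1) * stem), rng)
        stems[region] = variant
    hap_seqs = []
    for i, h in enumerate(spec.haplotypes):
        unique = len(h.copies) == 1
        seq = (stems[next(iter(h.copies))] if unique else root).copy()
        if h.n_mut > 0:
            extra = rng.choice(
                np.arange(free_start, L), size=h.n_mut - 1, replace=False
            )
            substitute(seq, np.r_[i, extra], rng)
        hap_seqs.append(seq.tobytes().decode("ascii"))
    # emit records grouped by region, ids unique per region
    regions: dict[str, list[tuple[str, str]]] = {}
    for h, seq in zip(spec.haplotypes, hap_seqs):
        for region, copies in h.copies.items():
            regions.setdefault(region, []).extend([(h.key, seq)] * copies)
    ids, regs, seqs = [], [], []
    for region, entries in regions.items():
        for k, (_, seq) in enumerate(entries, start=1):
            ids.append(f"{region}_{k:03d}")
            regs.append(region)
            seqs.append(seq)
    aln = Alignment(tuple(ids), tuple(regs), tuple(seqs))
    # truth from the realized sequences (spec entries could collide)
    where: dict[str, set[str]] = {}
    for h, seq in zip(spec.haplotypes, hap_seqs):
        where.setdefault(seq, set()).update(h.copies)
    hu: dict[str, int] = {r: 0 for r in regions}
    for members in where.values():
        if len(members) == 1:
            hu[next(iter(members))] += 1
    truth = {
        "n_haplotypes": len(where),
        "n_unique": sum(len(m) == 1 for m in where.values()),
        "hu_per_region": hu,
        "n_sequences": aln.n,
    }
    return aln, truth


@dataclass
class World:
    """A fully generated synthetic study system plus its ground truth."""

    spec: WorldSpec
    landscape: Landscape
    grid: CoarseGrid  # with presence flags set
    features: object  # baseline feature table (DataFrame)
    true_probs: np.ndarray
    timeslices: TimeSliceSet
    futures: dict[str, dict[str, Raster]]
    alignment: Alignment
    sequence_truth: dict


def make_world(spec: WorldSpec | None = None) -> World:
    """Generate the complete default world (deterministic in ``spec.seed``)."""
    spec = spec or WorldSpec()
    landscape = make_landscape(spec)
    grid, probs = make_occupancy(landscape, spec)
    feats = extract_features(landscape.climate, grid)
    ts = make_timeseries(spec, landscape)
    futures = {s: make_future(spec, landscape, s) for s in spec.scenarios}
    aln, truth = make_sequences(spec)
    return World(
        spec=spec,
        landscape=landscape,
        grid=grid,
        features=feats,
        true_probs=probs,
        timeslices=ts,
        futures=futures,
        alignment=aln,
        sequence_truth=truth,
    )


def planted_warming_offset(world: World) -> tuple[str, float, int]:
    """A uniform warming that extinguishes exactly one region.

    Under the default true model (logistic in minimum warm-quarter
    temperature) a uniform warming of ``dt`` kills a cell when its
    ``t_warm_min`` rises past the suitability boundary; a region dies when
    its coldest occupied cell does.  Returns the most exposed region, a
    warming chosen halfway between extinguishing it and extinguishing any
    second region, and the region's planted unique-haplotype count.
    """
    spec = world.spec
    coefs = dict(spec.true_coefs)
    if set(coefs) != {"t_warm_min"} or coefs["t_warm_min"] >= 0:
        raise ValueError("planted offset requires the default t_warm_min model")
    b = coefs["t_warm_min"]
    thr = spec.occupancy_threshold
    t_star = (np.log(thr / (1 - thr)) - spec.true_intercept) / b
    tmin = world.features["t_warm_min"].to_numpy(dtype=float)
    region = world.grid.region_id.ravel()
    occ = world.grid.presence.ravel()
    resistance = {}
    for r in world.grid.regions():
        cells = occ & (region == r)
        if cells.any():
            resistance[r] = float(t_star - tmin[cells].min())
    ordered = sorted(resistance.items(), key=lambda kv: kv[1])
    target, r0 = ordered[0]
    r1 = ordered[1][1]
    if r1 - r0 < 1e-6:
        raise ValueError("no warming gap between the two most exposed regions")
    hu = world.sequence_truth["hu_per_region"].get(target, 0)
    return target, (r0 + r1) / 2.0, int(hu)


def write_world(world: World, outdir: str | Path) -> dict:
    """Write a world to disk in the pipeline's exchange formats.

    Produces the alignment FASTA and region CSV, the coarse grid CSV,
    baseline and future-scenario ASCII rasters, a slice manifest
    (``age_ka,var,anomaly_path,ice_path``) with one ASCII grid per anomaly
    and ice mask, and a ``truth.json`` carrying the generator's ground
    truth.  Returns a dict of the paths written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "alignment.fasta"
    with open(fasta, "w") as fh:
        for sid, seq in zip(world.alignment.sample_ids, world.alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")
    regions_csv = out / "regions.csv"
    with open(regions_csv, "w") as fh:
        fh.write("sample_id,region_id\n")
        for sid, r in zip(world.alignment.sample_ids, world.alignment.region_ids):
            fh.write(f"{sid},{r}\n")
    grid_csv = out / "grid.csv"
    world.grid.write_csv(grid_csv)
    paths = {
        "fasta": str(fasta),
        "regions_csv": str(regions_csv),
        "grid_csv": str(grid_csv),
        "baseline": {},
        "futures": {},
        "slice_manifest": str(out / "slices.csv"),
        "truth": str(out / "truth.json"),
    }
    for v in VARIABLES:
        p = out / f"baseline_{v}.asc"
        world.landscape.climate[v].write_ascii(p)
        paths["baseline"][v] = str(p)
    world.landscape.elevation.write_ascii(out / "elevation.asc")
    for name, layers in world.futures.items():
        paths["futures"][name] = {}
        for v in VARIABLES:
            p = out / f"future_{name}_{v}.asc"
            layers[v].write_ascii(p)
            paths["futures"][name][v] = str(p)
    sdir = out / "slices"
    sdir.mkdir(exist_ok=True)
    with open(out / "slices.csv", "w") as fh:
        fh.write("age_ka,var,anomaly_path,ice_path\n")
        for sl in world.timeslices.slices:
            ice_p = sdir / f"ice_{sl.age_ka}ka.asc"
            sl.ice.write_ascii(ice_p, fmt="%.0f")
            for v in VARIABLES:
                p = sdir / f"anom_{sl.age_ka}ka_{v}.asc"
                sl.anomalies[v].write_ascii(p)
                fh.write(f"{sl.age_ka},{v},{p},{ice_p}\n")
    truth = {
        "seed": world.spec.seed,
        "occupancy_threshold": world.spec.occupancy_threshold,
        "true_intercept": world.spec.true_intercept,
        "true_coefs": dict(world.spec.true_coefs),
        "n_presences": int(world.grid.presence.sum()),
        "true_probs": [None if np.isnan(p) else round(float(p), 10) for p in world.true_probs],
        **world.sequence_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return paths
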