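"""Pipeline orchestration: one config in, a reproducible report bundle out.

Stages run in the study's order — haplotype diversity, ensemble fitting on
the current climate, millennial hindcasting with the stability surface,
then per-scenario future risk — and every stage writes its outputs to the
bundle directory as plain files so results can be inspected or reused
without rerunning the whole analysis.  A manifest records the config, its
hash, the seed and library versions, which is enough to reproduce the
bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .paleo import TimeSlice, TimeSliceSet, project_timeslices, stability_surface
from .popgen import (
    Alignment,
    amova_phi,
    build_network,
    collapse_haplotypes,
    crop_and_filter,
    diversity_table,
)
from .rasters import CoarseGrid, Raster, VARIABLES
from .risk import (
    ThresholdSpec,
    classify_cells,
    derive_threshold,
    haplotypes_at_risk,
    range_change,
)
from .sdm import (
    CommitteeConfig,
    extract_features,
    fit_committee,
    predict_ensemble,
    sample_pseudo_absences,
)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("refugia")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs, knobs and seeds of one pipeline run."""

    outdir: str
    fasta: str
    regions_csv: str
    grid_csv: str
    baseline: dict[str, str]  # variable name -> fine raster path
    slice_manifest: str
    futures: dict[str, dict[str, str]]  # scenario -> variable -> path
    coarse_cellsize: float = 50.0
    factor: int = 10
    scenarios: list[str] = field(default_factory=lambda: ["low", "high"])
    threshold_mode: str = "range-edge"
    threshold_value: float = 0.49
    buffer_km: float = 250.0
    pa_ratio: float = 3.0
    auc_gate: float = 0.85
    split_fraction: float = 0.70
    connection_limit: int | None = None
    amova_permutations: int = 999
    region_alias: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(path: str, fieldname: str) -> None:
    if not Path(path).exists():
        raise ValueError(f"config field {fieldname!r}: path does not exist: {path}")


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Check paths, variable sets and region cross-references; fail by name."""
    _require(config.fasta, "fasta")
    _require(config.regions_csv, "regions_csv")
    _require(config.grid_csv, "grid_csv")
    _require(config.slice_manifest, "slice_manifest")
    for v in VARIABLES:
        if v not in config.baseline:
            raise ValueError(f"config field 'baseline' missing variable {v!r}")
        _require(config.baseline[v], f"baseline[{v}]")
    for s in config.scenarios:
        if s not in config.futures:
            raise ValueError(f"scenario {s!r} has no entry in 'futures'")
        for v in VARIABLES:
            if v not in config.futures[s]:
                raise ValueError(f"futures[{s}] missing variable {v!r}")
            _require(config.futures[s][v], f"futures[{s}][{v}]")
    ThresholdSpec(config.threshold_mode, config.threshold_value)
    # region ids must reconcile between genetics and the spatial layer
    genetic = set(pd.read_csv(config.regions_csv)["region_id"])
    grid = CoarseGrid.read_csv(
        config.grid_csv, config.coarse_cellsize, config.factor
    )
    spatial = {config.region_alias.get(r, r) for r in grid.regions()} | set(
        grid.regions()
    )
    dangling = sorted(genetic - spatial)
    if dangling:
        raise ValueError(
            f"region ids in genetics but not in the spatial layer: {dangling}"
        )
    return config


def _read_slices(config: PipelineConfig, baseline: dict[str, Raster]) -> TimeSliceSet:
    manifest = pd.read_csv(config.slice_manifest)
    slices = []
    for age, sub in manifest.groupby("age_ka", sort=True):
        anomalies = {
            row["var"]: Raster.read_ascii(row["anomaly_path"])
            for _, row in sub.iterrows()
        }
        ice = Raster.read_ascii(sub["ice_path"].iloc[0])
        slices.append(TimeSlice(age_ka=int(age), anomalies=anomalies, ice=ice))
    slices.sort(key=lambda s: -s.age_ka)
    return TimeSliceSet(slices=tuple(slices), baseline=baseline)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    validate_config(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {"stages": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as e:  # noqa: BLE001
                raise PipelineError(name, e) from e
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, timings[name])
            return result

        return wrap

    # --- genetics ---------------------------------------------------------
    def _popgen():
        aln = Alignment.from_fasta(config.fasta, config.regions_csv)
        aln = crop_and_filter(aln)
        table = collapse_haplotypes(aln)
        div = diversity_table(table, aln)
        div.to_csv(out / "diversity.csv", index=False)
        table.to_frame().to_csv(out / "haplotypes.csv", index=False)
        net = build_network(table, config.connection_limit)
        net.write_edgelist_csv(out / "network_edges.csv")
        net.write_gml(out / "network.gml")
        amova = amova_phi(
            aln, n_permutations=config.amova_permutations, seed=config.seed
        )
        return aln, table, div, amova

    aln, table, div, amova = stage("popgen")(_popgen)
    summary["stages"]["popgen"] = {
        "n_sequences": aln.n,
        "retained_length": aln.length,
        "n_haplotypes": table.n_haplotypes,
        "amova_phi": round(amova.phi, 4),
        "amova_p": amova.p_value,
    }

    # --- current-climate ensemble ----------------------------------------
    def _sdm():
        grid = CoarseGrid.read_csv(
            config.grid_csv, config.coarse_cellsize, config.factor
        )
        baseline = {v: Raster.read_ascii(config.baseline[v]) for v in VARIABLES}
        feats = extract_features(baseline, grid)
        labels = sample_pseudo_absences(
            grid, buffer_km=config.buffer_km, ratio=config.pa_ratio, seed=config.seed
        )
        model = fit_committee(
            feats,
            labels,
            CommitteeConfig(
                inclusion_threshold=config.auc_gate,
                split_fraction=config.split_fraction,
                seed=config.seed,
            ),
        )
        model.to_json(out / "model.json")
        current = predict_ensemble(model, feats, tag="current")
        current.to_raster(grid).write_ascii(out / "suitability_current.asc")
        return grid, baseline, feats, model, current

    grid, baseline, feats, model, current = stage("sdm")(_sdm)
    summary["stages"]["sdm"] = {
        "n_presences": int(grid.presence.sum()),
        "members": {
            m.name: {"auc": round(m.holdout_auc, 4), "included": m.included}
            for m in model.members
        },
    }

    # --- hindcast and stability ------------------------------------------
    def _paleo():
        slices = _read_slices(config, baseline)
        maps = project_timeslices(model, slices, grid)
        for m in maps:
            m.to_raster(grid).write_ascii(out / f"suitability_{m.tag}.asc")
        stab = stability_surface(maps)
        stab.write_csv(out / "refugia.csv")
        Raster(
            stab.sums.reshape(grid.nrows, grid.ncols), grid.cellsize
        ).write_ascii(out / "stability.asc")
        return maps, stab

    maps, stab = stage("paleo")(_paleo)
    summary["stages"]["paleo"] = {
        "n_maps": len(maps),
        "n_refugium_cells": int(stab.flag.sum()),
    }

    # --- future scenarios and haplotype risk ------------------------------
    def _risk():
        thr = derive_threshold(
            current,
            grid,
            ThresholdSpec(config.threshold_mode, config.threshold_value),
        )
        fate_frames, report_rows, risks = [], [], {}
        for s in config.scenarios:
            fut_layers = {
                v: Raster.read_ascii(config.futures[s][v]) for v in VARIABLES
            }
            fmap = predict_ensemble(model, extract_features(fut_layers, grid), tag=s)
            fmap.to_raster(grid).write_ascii(out / f"suitability_future_{s}.asc")
            fates = classify_cells(current, fmap, grid, thr, scenario=s)
            fate_frames.append(fates.to_frame())
            report = range_change(fates, grid, config.region_alias)
            report.insert(0, "scenario", s)
            hr = haplotypes_at_risk(
                range_change(fates, grid), div, table=table, scenario=s
            )
            report_rows.append(report)
            risks[s] = hr
        pd.concat(fate_frames).to_csv(out / "fates.csv", index=False)
        full_report = pd.concat(report_rows)
        hu_col = {
            r: int(h) for r, h in zip(div["region"], div["Hu"]) if r != "All"
        }
        full_report["Hu"] = [
            hu_col.get(r, "") for r in full_report["region"]
        ]
        full_report.to_csv(out / "risk_report.csv", index=False)
        return thr, risks, full_report

    thr, risks, report = stage("risk")(_risk)
    summary["stages"]["risk"] = {
        "threshold": round(thr, 4),
        "Hr": {s: r.hr for s, r in risks.items()},
        "lost_regions": {s: list(r.lost_regions) for s, r in risks.items()},
        "at_risk_haplotypes": {
            s: list(r.at_risk_haplotypes) for s, r in risks.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "refugia_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
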