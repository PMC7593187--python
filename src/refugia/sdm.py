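"""Ensemble species-distribution modeling on the coarse occupancy grid.

The species is assumed to be limited by climatic extremes within each
coarse (50-km scale) cell, so the predictors are not cell means: for each
of the four seasonal base variables (temperature and precipitation of the
coldest and warmest quarters) the coldest/warmest and driest/wettest fine
cell inside the coarse cell is used, giving eight features per cell.

Fitting follows the ensemble recipe common in the SDM literature: several
model families are trained on a stratified 70% split against presences and
buffered pseudo-absences, scored by ROC AUC on the 30% holdout, and only
members whose AUC clears an inclusion gate (default 0.85) enter the
ensemble; the ensemble probability is the unweighted mean of included
members (AUC-weighted mean available behind a flag).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .rasters import CoarseGrid, Raster, SuitabilityMap, VARIABLES

__all__ = [
    "FEATURE_COLUMNS",
    "extract_features",
    "sample_pseudo_absences",
    "roc_auc",
    "CommitteeConfig",
    "EnsembleMember",
    "EnsembleModel",
    "fit_committee",
    "predict_ensemble",
    "morans_i",
]

FEATURE_COLUMNS = tuple(f"{v}_{m}" for v in VARIABLES for m in ("min", "max"))


def extract_features(
    fine_layers: Mapping[str, Raster], grid: CoarseGrid
) -> pd.DataFrame:
    """Extreme-cell feature table: per coarse cell, min and max of each layer.

    ``fine_layers`` maps the four base variable names to fine rasters whose
    shape is ``(nrows*factor, ncols*factor)``.  Returns a DataFrame indexed
    by flat cell id with the eight columns of :data:`FEATURE_COLUMNS`;
    coarse cells without a single valid fine cell get NaN rows (masked)
    and a warning.
    """
    missing = [v for v in VARIABLES if v not in fine_layers]
    if missing:
        raise ValueError(f"missing climate layers: {missing}")
    shapes = {fine_layers[v].shape for v in VARIABLES}
    if len(shapes) != 1:
        raise ValueError("climate layers do not share geometry")
    nrows, ncols, f = grid.nrows, grid.ncols, grid.factor
    if shapes.pop() != (nrows * f, ncols * f):
        raise ValueError("fine layer shape does not match grid blocks")
    out = {}
    for v in VARIABLES:
        blocks = fine_layers[v].values.reshape(nrows, f, ncols, f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            out[f"{v}_min"] = np.nanmin(blocks, axis=(1, 3)).ravel()
            out[f"{v}_max"] = np.nanmax(blocks, axis=(1, 3)).ravel()
    table = pd.DataFrame(out, index=grid.cell_ids(), columns=list(FEATURE_COLUMNS))
    table.index.name = "cell_id"
    n_masked = int(table.isna().any(axis=1).sum())
    if n_masked:
        warnings.warn(f"{n_masked} coarse cells have no valid fine cells; masked")
    return table


def sample_pseudo_absences(
    grid: CoarseGrid,
    buffer_km: float = 250.0,
    ratio: float = 3.0,
    seed: int | None = None,
) -> pd.Series:
    """Presences plus buffered pseudo-absences as a 0/1 label series.

    Candidate absences are valid non-presence cells whose center lies
    within ``buffer_km`` of any presence center (planar distance; the
    buffer keeps absences out of remote but climatically suitable areas
    never surveyed as occupied).  ``min(ratio * n_presences, n_candidates)``
    of them are drawn uniformly without replacement, seeded.
    """
    pres = grid.presence_ids()
    if pres.size == 0:
        raise ValueError("grid has no presences")
    x, y = grid.centers()
    px, py = x[pres], y[pres]
    cand_mask = grid.valid.ravel() & ~grid.presence.ravel()
    cand = np.flatnonzero(cand_mask)
    d2 = (x[cand, None] - px[None, :]) ** 2 + (y[cand, None] - py[None, :]) ** 2
    within = (d2.min(axis=1) <= buffer_km**2)
    cand = cand[within]
    if cand.size == 0:
        raise ValueError("buffer excludes all absences")
    k = min(int(round(ratio * pres.size)), cand.size)
    rng = np.random.default_rng(seed)
    absent = rng.choice(cand, size=k, replace=False)
    labels = pd.Series(
        np.r_[np.ones(pres.size, dtype=int), np.zeros(k, dtype=int)],
        index=np.r_[pres, absent],
        name="label",
    )
    labels.index.name = "cell_id"
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by rank statistics.

    Equivalent to pair counting: (concordant + 0.5 * tied) / (n1 * n0).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks handle ties
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


class RectilinearEnvelope:
    """Surface-range-envelope classifier.

    Scores 1 inside the axis-aligned box spanned by central percentiles of
    the presence training features, else 0 — the classic climate-envelope
    ("SRE") member of SDM ensembles.
    """

    def __init__(self, quantile: float = 0.025):
        self.quantile = quantile

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RectilinearEnvelope":
        pres = X[np.asarray(y) == 1]
        self.lo_ = np.quantile(pres, self.quantile, axis=0)
        self.hi_ = np.quantile(pres, 1 - self.quantile, axis=0)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        inside = ((X >= self.lo_) & (X <= self.hi_)).all(axis=1).astype(float)
        return np.c_[1 - inside, inside]

    def get_params(self) -> dict:
        return {"quantile": self.quantile}


def _default_families(seed: int) -> dict[str, object]:
    """The four committee families: linear, additive-spline, boosted trees,
    rectilinear envelope."""
    return {
        "glm": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, C=1.0)
        ),
        "gam": make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=5, degree=3),
            LogisticRegression(max_iter=1000, C=1.0),
        ),
        "gbm": GradientBoostingClassifier(random_state=seed),
        "sre": RectilinearEnvelope(),
    }


@dataclass
class CommitteeConfig:
    inclusion_threshold: float = 0.85
    split_fraction: float = 0.70
    seed: int = 0
    auc_weighted: bool = False
    families: tuple[str, ...] = ("glm", "gam", "gbm", "sre")


@dataclass
class EnsembleMember:
    name: str
    model: object
    holdout_auc: float
    included: bool


@dataclass
class EnsembleModel:
    """A fitted, ROC-gated model committee."""

    members: list[EnsembleMember]
    inclusion_threshold: float
    split_fraction: float
    seed: int
    feature_columns: tuple[str, ...]
    auc_weighted: bool = False
    holdout_ids: tuple[int, ...] = ()  # cell ids of the 30% evaluation split

    @property
    def included(self) -> list[EnsembleMember]:
        return [m for m in self.members if m.included]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [m.name for m in self.members],
                "holdout_auc": [m.holdout_auc for m in self.members],
                "included": [m.included for m in self.members],
            }
        )

    def to_json(self, path: str | Path) -> None:
        """Dump family names, AUCs, gate decisions and seed (not weights)."""
        payload = {
            "inclusion_threshold": self.inclusion_threshold,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
            "auc_weighted": self.auc_weighted,
            "feature_columns": list(self.feature_columns),
            "members": [
                {
                    "family": m.name,
                    "holdout_auc": m.holdout_auc,
                    "included": m.included,
                }
                for m in self.members
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_committee(
    features: pd.DataFrame,
    labels: pd.Series,
    config: CommitteeConfig | None = None,
) -> EnsembleModel:
    """Train the committee on a stratified split and gate members by AUC.

    ``labels`` is a 0/1 series indexed by cell id (as returned by
    :func:`sample_pseudo_absences`); feature rows are looked up by id and
    must be unmasked.  A member is included iff its holdout AUC exceeds
    the inclusion threshold; an ensemble with no included member is an
    error.
    """
    cfg = config or CommitteeConfig()
    rows = features.loc[labels.index]
    if rows.isna().any().any():
        raise ValueError("labeled cells include masked feature rows")
    X = rows.to_numpy(dtype=float)
    y = labels.to_numpy(dtype=int)
    ids = labels.index.to_numpy()
    X_tr, X_te, y_tr, y_te, _, ids_te = train_test_split(
        X,
        y,
        ids,
        train_size=cfg.split_fraction,
        stratify=y,
        random_state=cfg.seed,
    )
    members = []
    for name in cfg.families:
        model = _default_families(cfg.seed)[name]
        model.fit(X_tr, y_tr)
        auc = roc_auc(model.predict_proba(X_te)[:, 1], y_te)
        members.append(
            EnsembleMember(name, model, auc, auc > cfg.inclusion_threshold)
        )
    ensemble = EnsembleModel(
        members=members,
        inclusion_threshold=cfg.inclusion_threshold,
        split_fraction=cfg.split_fraction,
        seed=cfg.seed,
        feature_columns=tuple(features.columns),
        auc_weighted=cfg.auc_weighted,
        holdout_ids=tuple(int(i) for i in ids_te),
    )
    if not ensemble.included:
        raise ValueError("empty ensemble: no member passed the ROC gate")
    return ensemble


def predict_ensemble(
    model: EnsembleModel, features: pd.DataFrame, tag: str = "current"
) -> SuitabilityMap:
    """Mean probability of the gated members per cell; masked rows stay NaN."""
    if tuple(features.columns) != model.feature_columns:
        raise ValueError("feature columns do not match the fitted model")
    ok = ~features.isna().any(axis=1).to_numpy()
    probs = np.full(len(features), np.nan)
    if ok.any():
        X = features.to_numpy(dtype=float)[ok]
        preds = np.stack([m.model.predict_proba(X)[:, 1] for m in model.included])
        if model.auc_weighted:
            w = np.array([m.holdout_auc for m in model.included])
            probs[ok] = (w[:, None] * preds).sum(0) / w.sum()
        else:
            probs[ok] = preds.mean(axis=0)
    return SuitabilityMap(probs=np.clip(probs, 0.0, 1.0), tag=tag)


def morans_i(
    values: Sequence[float],
    coords: np.ndarray,
    scheme: str = "rook",
) -> tuple[float, float]:
    """Moran's I with row-standardized weights and a randomization p-value.

    ``coords`` is (n, 2) cell-center coordinates.  ``rook`` links each
    point to its nearest-distance neighbors (edge-sharing cells on a
    regular grid); ``inverse-distance`` weights every pair by 1/d.  The
    p-value uses the normal approximation under the randomization
    assumption (two-sided).
    """
    z = np.asarray(values, dtype=float)
    pts = np.asarray(coords, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(z) == 0:
        raise ValueError("zero variance")
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    np.fill_diagonal(d, np.inf)
    if scheme == "rook":
        step = d.min()
        w = (d <= step * (1 + 1e-9)).astype(float)
    elif scheme == "inverse-distance":
        w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    rs = w.sum(axis=1, keepdims=True)
    if (rs == 0).any():
        raise ValueError("isolated point: empty weight row")
    w = w / rs
    zc = z - z.mean()
    s0 = w.sum()
    I = (n / s0) * float(zc @ w @ zc) / float(zc @ zc)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (zc**4).sum() / (zc**2).sum() ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    zscore = (I - e_i) / np.sqrt(var_i)
    p = 2 * stats.norm.sf(abs(zscore))
    return float(I), float(p)
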