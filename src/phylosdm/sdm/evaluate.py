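"""Occurrence handling, cross-validated evaluation and model selection.

The tuning protocol: candidate models over a regularisation-multiplier x
feature-class grid, k-fold cross-validation of presences against a shared
background sample, scored by test AUC, the train-test AUC difference, the
10% training omission rate (OR10) and AICc of the full-data model; the
candidate with the lowest delta-AICc wins, with OR10/AUC_diff/AUC_test as
tie-breakers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ..errors import ParameterError, ProjectionError, RasterError, SelectionError
from .maxent import MaxEntSDM
from .raster import EARTH_RADIUS_KM, RasterStack

__all__ = [
    "OccurrenceSet",
    "thin_occurrences",
    "sample_background",
    "auc_presence_background",
    "threshold_10pct",
    "ThresholdInfo",
    "evaluate_cv",
    "select_model",
    "predict_map",
    "binarize",
    "DEFAULT_RM_GRID",
    "DEFAULT_FEATURE_CLASSES",
]

DEFAULT_RM_GRID = tuple(np.arange(0.5, 4.01, 0.5))
DEFAULT_FEATURE_CLASSES = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")


@dataclass(frozen=True)
class OccurrenceSet:
    """Presence localities (lon, lat) for one species."""

    points: np.ndarray  # (n, 2) lon, lat
    species: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "points", np.asarray(self.points, dtype=float).reshape(-1, 2)
        )

    @property
    def n(self) -> int:
        return len(self.points)

    @classmethod
    def read_csv(cls, path, species: str = "") -> "OccurrenceSet":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "lon" not in cols or "lat" not in cols:
            raise ParameterError("occurrence CSV needs lon and lat columns")
        return cls(df[[cols["lon"], cols["lat"]]].to_numpy(), species)

    def write_csv(self, path) -> None:
        pd.DataFrame(self.points, columns=["lon", "lat"]).to_csv(path, index=False)

    def snap_to_cells(self, stack: RasterStack) -> np.ndarray:
        """Unique valid (row, col) cells containing the points."""
        mask = stack.mask
        cells: list[tuple[int, int]] = []
        seen = set()
        for lon, lat in self.points:
            r, c = stack.geometry.cell_of(lon, lat)
            if not mask[r, c]:
                raise RasterError(
                    f"occurrence ({lon}, {lat}) falls on a nodata cell"
                )
            if (r, c) not in seen:
                seen.add((r, c))
                cells.append((r, c))
        return np.array(cells, dtype=int)


def _great_circle_km(p: np.ndarray, q: np.ndarray) -> float:
    lon1, lat1, lon2, lat2 = map(math.radians, (p[0], p[1], q[0], q[1]))
    a = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def thin_occurrences(occ: OccurrenceSet, min_distance_km: float) -> OccurrenceSet:
    """Greedy spatial rarefaction.

    Exact duplicates are removed first; points are then scanned in a
    deterministic order (sorted by lon, then lat) and kept iff at least
    ``min_distance_km`` great-circle from every already-kept point.
    """
    if min_distance_km <= 0:
        raise ParameterError("min_distance_km must be positive")
    if occ.n == 0:
        return occ
    pts = np.unique(occ.points, axis=0)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    kept: list[np.ndarray] = []
    for i in order:
        p = pts[i]
        if all(_great_circle_km(p, q) >= min_distance_km for q in kept):
            kept.append(p)
    return OccurrenceSet(np.array(kept), occ.species)


def sample_background(
    stack: RasterStack, n: int = 10_000, seed: int = 0,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Sample background cells uniformly without replacement.

    Returns (k, 2) (row, col) indices; ``n`` is capped at the number of
    available valid cells. ``exclude`` removes specific cells (e.g.
    presences) from the pool.
    """
    cells = stack.valid_cells()
    if exclude is not None and len(exclude):
        excl = {tuple(c) for c in np.asarray(exclude)}
        keep = [i for i, c in enumerate(map(tuple, cells)) if c not in excl]
        cells = cells[keep]
    rng = np.random.Generator(np.random.PCG64(seed))
    k = min(n, len(cells))
    idx = rng.choice(len(cells), size=k, replace=False)
    return cells[np.sort(idx)]


def auc_presence_background(
    scores_presence: np.ndarray, scores_background: np.ndarray
) -> float:
    """AUC via the Mann-Whitney rank statistic (ties get half credit)."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    ranks = rankdata(np.concatenate([sp, sb]))
    r1 = ranks[: len(sp)].sum()
    u = r1 - len(sp) * (len(sp) + 1) / 2.0
    return float(u / (len(sp) * len(sb)))


@dataclass(frozen=True)
class ThresholdInfo:
    rule: str
    value: float
    training_suitabilities: np.ndarray


def threshold_10pct(training_suitabilities: np.ndarray) -> ThresholdInfo:
    """10% training presence threshold.

    The ceil(0.1 * n)-th smallest training suitability, so that at least
    90% of training presences score at or above the threshold.
    """
    s = np.sort(np.asarray(training_suitabilities, dtype=float))
    n = len(s)
    if n == 0:
        raise ParameterError("no training suitabilities")
    k = max(1, math.ceil(0.1 * n))
    return ThresholdInfo("ten_percent_training_presence", float(s[k - 1]), s)


def evaluate_cv(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    rm_grid=DEFAULT_RM_GRID,
    feature_classes=DEFAULT_FEATURE_CLASSES,
    k_folds: int = 10,
    seed: int = 0,
    n_knots: int = 20,
    X_grid: np.ndarray | None = None,
    transform: str = "logistic",
) -> pd.DataFrame:
    """Cross-validated evaluation over the RM x feature-class grid.

    Returns one row per combination with mean test AUC, mean train-test
    AUC difference, mean OR10, AICc of the full-data model (nonzero
    coefficient count k; undefined and flagged when n - k - 1 <= 0) and
    delta-AICc relative to the grid minimum. ``X_grid`` supplies the cells
    over which raw output is renormalised for the AICc likelihood
    (defaults to the background sample).
    """
    X_presence = np.asarray(X_presence, dtype=float)
    X_background = np.asarray(X_background, dtype=float)
    n_pres = X_presence.shape[0]
    if n_pres < k_folds:
        raise ParameterError("need at least k_folds presences")
    if X_grid is None:
        X_grid = X_background
    rng = np.random.Generator(np.random.PCG64(seed))
    fold_of = np.array([i % k_folds for i in range(n_pres)])
    rng.shuffle(fold_of)
    y_full = np.concatenate([np.ones(n_pres), np.zeros(len(X_background))])
    rows = []
    for fc in feature_classes:
        for rm in rm_grid:
            model = MaxEntSDM(
                feature_classes=fc, rm=float(rm), n_knots=n_knots,
                transform=transform,
            )
            full = model.fit(np.vstack([X_presence, X_background]), y_full)
            k = full.k_
            lnL = full.log_likelihood(X_presence, X_grid)
            aicc = (
                2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1.0) / (n_pres - k - 1.0)
                if n_pres - k - 1 > 0
                else float("nan")
            )
            aucs_tr, aucs_te, or10s = [], [], []
            for f in range(k_folds):
                tr = X_presence[fold_of != f]
                te = X_presence[fold_of == f]
                if len(te) == 0 or len(tr) < 5:
                    continue
                m = MaxEntSDM(
                    feature_classes=fc, rm=float(rm), n_knots=n_knots,
                    transform=transform,
                ).fit(
                    np.vstack([tr, X_background]),
                    np.concatenate([np.ones(len(tr)), np.zeros(len(X_background))]),
                )
                s_tr = m.predict(tr)
                s_te = m.predict(te)
                s_bg = m.predict(X_background)
                aucs_tr.append(auc_presence_background(s_tr, s_bg))
                aucs_te.append(auc_presence_background(s_te, s_bg))
                thr = threshold_10pct(s_tr).value
                or10s.append(float(np.mean(s_te < thr)))
            rows.append(
                {
                    "rm": float(rm),
                    "fc": fc,
                    "auc_train": float(np.mean(aucs_tr)),
                    "auc_test": float(np.mean(aucs_te)),
                    "auc_diff": float(np.mean(np.array(aucs_tr) - np.array(aucs_te))),
                    "or10": float(np.mean(or10s)),
                    "k": k,
                    "lnL": lnL,
                    "aicc": aicc,
                    "converged": full.converged_,
                }
            )
    report = pd.DataFrame(rows)
    valid = report["aicc"].notna()
    if valid.any():
        report["delta_aicc"] = report["aicc"] - report.loc[valid, "aicc"].min()
    else:
        report["delta_aicc"] = float("nan")
    return report


def select_model(report: pd.DataFrame) -> tuple[float, str]:
    """Choose (RM, FC) by lowest delta-AICc.

    Exact ties are broken by lower OR10, then lower AUC_diff, then higher
    AUC_test (operationalising the convention of weighing overfitting
    diagnostics alongside AICc).
    """
    valid = report[report["aicc"].notna()].copy()
    if valid.empty:
        raise SelectionError("no combination has a defined AICc")
    valid = valid.sort_values(
        ["delta_aicc", "or10", "auc_diff", "auc_test"],
        ascending=[True, True, True, False],
        kind="stable",
    )
    best = valid.iloc[0]
    return float(best["rm"]), str(best["fc"])


def predict_map(
    model: MaxEntSDM,
    stack: RasterStack,
    layer_names: list[str],
    transform: str | None = None,
) -> np.ndarray:
    """Project a fitted model onto a raster stack.

    Features outside the training range are clamped (count available as
    ``model.n_clamped_``). Returns a 2-D suitability array with NaN
    outside the valid mask.
    """
    missing = [n for n in layer_names if n not in stack.layers]
    if missing:
        raise ProjectionError(f"stack lacks training layers: {missing}")
    cells = stack.valid_cells()
    X = stack.values_at(cells, layer_names)
    vals = model.predict(X, transform=transform)
    out = np.full((stack.geometry.n_rows, stack.geometry.n_cols), np.nan)
    out[cells[:, 0], cells[:, 1]] = vals
    return out


def binarize(suitability: np.ndarray, threshold: float) -> np.ndarray:
    """Presence/absence map: presence iff suitability >= threshold."""
    out = np.full(suitability.shape, np.nan)
    ok = ~np.isnan(suitability)
    out[ok] = (suitability[ok] >= threshold).astype(float)
    return out
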