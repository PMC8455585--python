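"""Latent-variable regression of activities on molecular fields.

The estimator is PLS1 (NIPALS) on column-centered descriptors: the classic
choice when a few dozen compounds face thousands of collinear lattice
columns.  The module follows the model/results idiom: :class:`FieldPLS` is
built from a descriptor matrix (usually via
:meth:`FieldPLS.from_field_matrix`) and ``fit()`` returns a
:class:`FieldPLSResults` carrying coefficients, training statistics
(r2, SEE, F), leave-one-out cross-validation (q2, SEP), and methods for
bootstrap validation, response scrambling, external prediction statistics
and stdev*coeff contour maps.

Conventions: columns whose value range falls below 2.0 kcal/mol are dropped
before fitting (signal-to-noise filter); SEE/SEP use an (n - ncomp - 1)
denominator; a model is flagged reliable when r2 > 0.90 and q2 > 0.50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fieldgen import FieldMatrix, GridSpec

__all__ = [
    "PLSModel",
    "FieldPLS",
    "FieldPLSResults",
    "ContourField",
    "column_filter",
    "fit_pls",
    "loo_q2",
    "select_components",
    "non_cv_stats",
    "external_r2pred",
    "bootstrap_validate",
    "y_scramble",
    "field_contributions",
    "stdev_coeff_map",
    "extract_contours",
]

#: reliability thresholds conventional for 3D-QSAR models
R2_RELIABLE = 0.90
Q2_RELIABLE = 0.50


# ---------------------------------------------------------------------------
# core decomposition


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 decomposition."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (p, a)
    x_loadings: np.ndarray    # (p, a)
    y_loadings: np.ndarray    # (a,)
    scores: np.ndarray        # (n, a)
    coef: np.ndarray          # (p,) regression vector on centered X

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_pls(X: np.ndarray, y: np.ndarray, ncomp: int) -> PLSModel:
    """NIPALS PLS1 on column-centered ``X`` and centered ``y``.

    No per-column variance scaling is applied (block scaling belongs to the
    descriptor assembly).  ``ncomp`` is capped at min(n-1, p); deflation of
    a numerically exhausted residual stops early with the achieved rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in input")
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    ncomp = min(ncomp, n - 1, p)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    a_used = 0
    for a in range(ncomp):
        w = E.T @ f
        wn = np.linalg.norm(w)
        if wn < 1e-12:
            break
        w /= wn
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pa)
        f = f - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        a_used += 1
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    if a_used == 0:
        coef = np.zeros(p)
    else:
        coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(a_used, x_mean, y_mean, W, P, q, T, coef)


# ---------------------------------------------------------------------------
# validation statistics (module-level, reused by the results object)


def loo_q2(X: np.ndarray, y: np.ndarray, ncomp: int) -> tuple[float, float]:
    """Leave-one-out q2 and SEP.

    q2 = 1 - PRESS / sum((y - ybar)^2) with each prediction made by a model
    that excludes the predicted sample; SEP = sqrt(PRESS / (n - ncomp - 1)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero variance in y: q2 undefined")
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        m = fit_pls(X[mask], y[mask], ncomp)
        press += float((y[i] - m.predict(X[i:i + 1])[0]) ** 2)
    q2 = 1.0 - press / sst
    dof = max(n - ncomp - 1, 1)
    sep = float(np.sqrt(press / dof))
    return q2, sep


def select_components(X: np.ndarray, y: np.ndarray, max_ncomp: int = 10
                      ) -> tuple[int, list[float]]:
    """Optimal component count by LOO q2; ties break toward fewer components."""
    if max_ncomp < 1:
        raise ValueError("max_ncomp must be >= 1")
    n, p = np.asarray(X).shape
    max_ncomp = min(max_ncomp, n - 2, p)
    q2s = []
    best, best_q2 = 1, -np.inf
    for a in range(1, max_ncomp + 1):
        q2, _ = loo_q2(X, y, a)
        q2s.append(q2)
        if q2 > best_q2 + 1e-12:
            best, best_q2 = a, q2
    return best, q2s


def non_cv_stats(model: PLSModel, X: np.ndarray, y: np.ndarray
                 ) -> tuple[float, float, float]:
    """Training r2, standard error of estimate, and F statistic."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    a = model.n_components
    if n <= a + 1:
        raise ValueError("too few samples for the component count")
    yhat = model.predict(X)
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    see = float(np.sqrt(sse / (n - a - 1)))
    f = (r2 / a) / ((1.0 - r2) / (n - a - 1)) if r2 < 1.0 else np.inf
    return r2, see, f


def external_r2pred(y_test: Sequence[float], yhat_test: Sequence[float],
                    train_mean: float) -> tuple[float, float, float]:
    """External predictive r2 for a held-out test set.

    PRES = sum((y - yhat)^2); SD = sum((y - train mean)^2);
    r2_pred = 1 - PRES/SD.
    """
    y = np.asarray(y_test, dtype=float).ravel()
    yhat = np.asarray(yhat_test, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("need matching, nonempty test vectors")
    pres = float(((y - yhat) ** 2).sum())
    sd = float(((y - train_mean) ** 2).sum())
    if sd == 0:
        raise ValueError("SD = 0: r2_pred undefined")
    return 1.0 - pres / sd, pres, sd


def bootstrap_validate(X: np.ndarray, y: np.ndarray, ncomp: int,
                       n_runs: int = 60, seed: int = 0
                       ) -> dict[str, float]:
    """Row-resampling bootstrap of the training fit (default 60 runs)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = len(y)
    r2s, sees = [], []
    for _ in range(n_runs):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) > 1 and np.ptp(y[idx]) > 0:
                break
        m = fit_pls(X[idx], y[idx], ncomp)
        r2, see, _ = non_cv_stats(m, X[idx], y[idx])
        r2s.append(r2)
        sees.append(see)
    return {
        "r2_boot_mean": float(np.mean(r2s)),
        "r2_boot_sd": float(np.std(r2s, ddof=1)),
        "see_boot_mean": float(np.mean(sees)),
        "n_runs": n_runs,
    }


def y_scramble(X: np.ndarray, y: np.ndarray, ncomp: int,
               n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Response-permutation null: refit on shuffled activities.

    The identity permutation is excluded.  Returns one row per permutation
    with the scrambled q2 and r2.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = len(y)
    rows = []
    for k in range(n_perm):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, np.arange(n)):
                break
        ys = y[perm]
        q2, _ = loo_q2(X, ys, ncomp)
        m = fit_pls(X, ys, ncomp)
        r2, _, _ = non_cv_stats(m, X, ys)
        rows.append({"perm": k, "q2": q2, "r2": r2})
    return pd.DataFrame(rows)


def field_contributions(coef: np.ndarray, X: np.ndarray,
                        column_labels: Sequence[str]) -> dict[str, float]:
    """Per-field fraction of total |coefficient * column stdev|."""
    labels = np.asarray(column_labels)
    sd = np.asarray(X, dtype=float).std(axis=0)
    weight = np.abs(np.asarray(coef) * sd)
    total = weight.sum()
    out = {}
    for name in dict.fromkeys(labels):  # preserve first-seen order
        share = weight[labels == name].sum()
        out[str(name)] = float(share / total) if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# contour maps


@dataclass
class ContourField:
    """stdev*coeff values per lattice point for each descriptor field."""

    grid: GridSpec
    values: dict[str, np.ndarray]
    favored_level: float = 80.0
    disfavored_level: float = 20.0

    def __post_init__(self) -> None:
        if not self.favored_level > self.disfavored_level:
            raise ValueError("favored_level must exceed disfavored_level")


def stdev_coeff_map(coef: np.ndarray, X: np.ndarray, kept_columns: np.ndarray,
                    column_labels: Sequence[str], grid: GridSpec,
                    field_names: Sequence[str]) -> ContourField:
    """Back-project column stdev x coefficient onto the lattice.

    ``kept_columns`` indexes the fitted columns within the full stacked
    matrix (fields concatenated in ``field_names`` order, each of length
    ``grid.n_points``); filtered-out columns map to zero.
    """
    sd = np.asarray(X, dtype=float).std(axis=0)
    vals = np.asarray(coef) * sd
    npts = grid.n_points
    full = np.zeros(len(field_names) * npts)
    full[np.asarray(kept_columns)] = vals
    values = {name: full[i * npts:(i + 1) * npts]
              for i, name in enumerate(field_names)}
    return ContourField(grid, values)


def extract_contours(field: ContourField) -> dict[str, dict[str, np.ndarray]]:
    """Favored/disfavored lattice point indices per field.

    Favored points have values at or above the ``favored_level`` percentile
    of the field's nonzero values, disfavored at or below the
    ``disfavored_level`` percentile (ties included on both sides).
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, v in field.values.items():
        nz = np.flatnonzero(v != 0)
        if nz.size == 0:
            out[name] = {"favored": np.array([], dtype=int),
                         "disfavored": np.array([], dtype=int)}
            continue
        hi = np.percentile(v[nz], field.favored_level)
        lo = np.percentile(v[nz], field.disfavored_level)
        out[name] = {
            "favored": nz[v[nz] >= hi],
            "disfavored": nz[v[nz] <= lo],
        }
    return out


def contours_to_dataframe(field: ContourField) -> pd.DataFrame:
    """CSV-ready table of (point index, x, y, z, field, value, polarity)."""
    pts = field.grid.points()
    regions = extract_contours(field)
    rows = []
    for name, reg in regions.items():
        for polarity in ("favored", "disfavored"):
            for idx in reg[polarity]:
                x, y, z = pts[idx]
                rows.append({"point": int(idx), "x": x, "y": y, "z": z,
                             "field": name, "value": field.values[name][idx],
                             "polarity": polarity})
    return pd.DataFrame(rows, columns=["point", "x", "y", "z", "field",
                                       "value", "polarity"])


# ---------------------------------------------------------------------------
# column filtering


def column_filter(X: np.ndarray, column_labels: Sequence[str],
                  threshold: float = 2.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop columns whose range (max - min over molecules) is below threshold.

    Returns (filtered X, kept column indices, kept labels).  Raises if the
    filter removes everything (degenerate model).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    X = np.asarray(X, dtype=float)
    rng = X.max(axis=0) - X.min(axis=0)
    kept = np.flatnonzero(rng >= threshold)
    if kept.size == 0:
        raise ValueError("column filter removed every descriptor column")
    labels = np.asarray(column_labels)
    return X[:, kept], kept, labels[kept]


# ---------------------------------------------------------------------------
# model / results objects


class FieldPLS:
    """Activity ~ molecular-field PLS model.

    Parameters
    ----------
    y : activities (pIC50), one per molecule.
    X : stacked descriptor matrix, molecules x columns.
    column_labels : per-column field tag (e.g. "S", "E", ...).
    grid, field_names, kept_columns : lattice bookkeeping used for contour
        back-projection; filled automatically by :meth:`from_field_matrix`.
    """

    def __init__(self, y, X, column_labels=None, grid: GridSpec | None = None,
                 field_names: Sequence[str] | None = None,
                 kept_columns: np.ndarray | None = None,
                 molecule_ids: Sequence[str] | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        n_cols = self.X.shape[1]
        self.column_labels = (np.asarray(column_labels) if column_labels is not None
                              else np.full(n_cols, "X", dtype=object))
        self.grid = grid
        self.field_names = list(field_names) if field_names else list(
            dict.fromkeys(self.column_labels))
        self.kept_columns = (np.asarray(kept_columns) if kept_columns is not None
                             else np.arange(n_cols))
        self.molecule_ids = list(molecule_ids) if molecule_ids else [
            f"m{i}" for i in range(self.X.shape[0])]

    @classmethod
    def from_field_matrix(cls, fm: FieldMatrix, activities: Sequence[float],
                          filter_threshold: float = 2.0) -> "FieldPLS":
        """Build from an assembled :class:`FieldMatrix`, applying the
        column-range filter (default 2.0 kcal/mol, on the scaled blocks)."""
        X, labels = fm.stacked()
        Xf, kept, kept_labels = column_filter(X, labels, filter_threshold)
        return cls(activities, Xf, kept_labels, grid=fm.grid,
                   field_names=fm.field_names, kept_columns=kept,
                   molecule_ids=fm.molecule_ids)

    def fit(self, ncomp: int | None = None, max_ncomp: int = 10
            ) -> "FieldPLSResults":
        """Fit; when ``ncomp`` is None the count is chosen by LOO q2."""
        if ncomp is None:
            ncomp, q2_path = select_components(self.X, self.y, max_ncomp)
        else:
            q2_path = None
        model = fit_pls(self.X, self.y, ncomp)
        return FieldPLSResults(self, model, q2_path)


class FieldPLSResults:
    """Fitted molecular-field PLS model with its validation statistics."""

    def __init__(self, model_spec: FieldPLS, plsmodel: PLSModel,
                 q2_path: list[float] | None = None):
        self.model = model_spec
        self.pls = plsmodel
        self.n_components = plsmodel.n_components
        self.q2_path = q2_path
        self.fittedvalues = plsmodel.predict(model_spec.X)
        self.r2, self.see, self.fvalue = non_cv_stats(
            plsmodel, model_spec.X, model_spec.y)
        self.q2, self.sep = loo_q2(model_spec.X, model_spec.y,
                                   plsmodel.n_components)

    # -- basic accessors ----------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Regression coefficients on the (centered) kept columns."""
        return self.pls.coef

    @property
    def train_mean(self) -> float:
        return float(self.model.y.mean())

    @property
    def reliable(self) -> bool:
        """Conventional reliability flag: r2 > 0.90 and q2 > 0.50."""
        return self.r2 > R2_RELIABLE and self.q2 > Q2_RELIABLE

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict activities for new rows of the kept-column matrix."""
        return self.pls.predict(X)

    def predict_field_matrix(self, fm: FieldMatrix) -> np.ndarray:
        """Predict from a full :class:`FieldMatrix` on the training lattice."""
        X, _ = fm.stacked()
        return self.predict(X[:, self.model.kept_columns])

    # -- validation ---------------------------------------------------------
    def external_validation(self, y_test, yhat_test) -> dict[str, float]:
        r2p, pres, sd = external_r2pred(y_test, yhat_test, self.train_mean)
        return {"r2_pred": r2p, "PRES": pres, "SD": sd}

    def bootstrap(self, n_runs: int = 60, seed: int = 0) -> dict[str, float]:
        return bootstrap_validate(self.model.X, self.model.y,
                                  self.n_components, n_runs, seed)

    def scramble(self, n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
        return y_scramble(self.model.X, self.model.y, self.n_components,
                          n_perm, seed)

    def field_contributions(self) -> dict[str, float]:
        return field_contributions(self.pls.coef, self.model.X,
                                   self.model.column_labels)

    def contour_field(self) -> ContourField:
        if self.model.grid is None:
            raise ValueError("model was built without lattice bookkeeping")
        return stdev_coeff_map(self.pls.coef, self.model.X,
                               self.model.kept_columns,
                               self.model.column_labels, self.model.grid,
                               self.model.field_names)

    # -- reporting ----------------------------------------------------------
    def report(self) -> dict:
        """JSON-serializable validation report."""
        return {
            "n_samples": int(len(self.model.y)),
            "n_columns": int(self.model.X.shape[1]),
            "optimal_ncomp": int(self.n_components),
            "q2": self.q2,
            "sep": self.sep,
            "r2": self.r2,
            "see": self.see,
            "F": self.fvalue,
            "reliable": bool(self.reliable),
            "field_contributions": self.field_contributions(),
        }

    def summary(self) -> str:
        rep = self.report()
        lines = [
            "Molecular-field PLS regression",
            "=" * 46,
            f"{'n compounds':<28}{rep['n_samples']:>18}",
            f"{'n descriptor columns':<28}{rep['n_columns']:>18}",
            f"{'components (LOO-selected)':<28}{rep['optimal_ncomp']:>18}",
            f"{'q2 (LOO)':<28}{rep['q2']:>18.4f}",
            f"{'SEP':<28}{rep['sep']:>18.4f}",
            f"{'r2':<28}{rep['r2']:>18.4f}",
            f"{'SEE':<28}{rep['see']:>18.4f}",
            f"{'F':<28}{rep['F']:>18.2f}",
            f"{'reliable (r2>0.9, q2>0.5)':<28}{str(rep['reliable']):>18}",
            "-" * 46,
            "field contributions:",
        ]
        for name, frac in rep["field_contributions"].items():
            lines.append(f"  {name:<10}{frac:>10.3f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Serialize the fitted model (JSON) for later prediction."""
        payload = {
            "n_components": int(self.n_components),
            "x_mean": self.pls.x_mean.tolist(),
            "y_mean": self.pls.y_mean,
            "coef": self.pls.coef.tolist(),
            "kept_columns": np.asarray(self.model.kept_columns).tolist(),
            "column_labels": [str(c) for c in self.model.column_labels],
            "field_names": self.model.field_names,
            "grid": None if self.model.grid is None else {
                "origin": list(self.model.grid.origin),
                "spacing": self.model.grid.spacing,
                "dims": list(self.model.grid.dims),
            },
            "stats": {k: v for k, v in self.report().items()
                      if k != "field_contributions"},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> dict:
    """Load a serialized model payload (see :meth:`FieldPLSResults.save`)."""
    payload = json.loads(Path(path).read_text())
    payload["x_mean"] = np.asarray(payload["x_mean"])
    payload["coef"] = np.asarray(payload["coef"])
    payload["kept_columns"] = np.asarray(payload["kept_columns"], dtype=int)
    if payload.get("grid"):
        g = payload["grid"]
        payload["grid"] = GridSpec(tuple(g["origin"]), g["spacing"], tuple(g["dims"]))
    return payload


def predict_with_payload(payload: dict, fm: FieldMatrix) -> np.ndarray:
    """Predict activities for a :class:`FieldMatrix` using a saved model."""
    X, _ = fm.stacked()
    Xk = X[:, payload["kept_columns"]]
    return (Xk - payload["x_mean"]) @ payload["coef"] + payload["y_mean"]
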