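"""The combined index: a cross-validated linear risk score over collagen features.

Construction follows the published recipe: min-max normalize every feature to
[0, 1]; run sequential forward selection with a least-squares
residual-sum-of-squares criterion against the 0/1 early-recurrence label;
fit the selected features by ordinary multivariable linear regression; and
validate by leave-one-out cross-validation (n fold models, each scoring the
single case it never saw).  The shipped published model carries the 18
printed coefficients and intercept 3.838; indices above the published 0.501
cutoff flag high early-recurrence risk (strictly greater).

The estimator class :class:`CombinedIndexRegressor` wraps the construction in
scikit-learn conventions (``fit``/``predict``/``get_params``, fitted
attributes with a trailing underscore); the module-level functions mirror the
individual construction steps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .taxonomy import DEFAULT_TAXONOMY, FeatureTaxonomy

#: published decision threshold on the combined index (strict >)
PUBLISHED_CUTOFF = 0.501

#: published 18-feature model: (feature name, coefficient)
PUBLISHED_COEFFICIENTS: tuple[tuple[str, float], ...] = (
    ("SHG", 4.300),
    ("StrOrientation", 1.280),
    ("StrAreaPA", -2.413),
    ("StrAreaPD", -1.269),
    ("NoThickStrS", 3.182),
    ("NoThinStrSA", -2.486),
    ("Fibrillar", -2.591),
    ("NoThickStrF", -1.889),
    ("NoThickStrFA", 1.735),
    ("NoShortStr/NoLongStr", -3.733),
    ("StrLengthP/StrWidthP", -0.859),
    ("NoThickStrPD/NoStrPD", -0.771),
    ("NoThinStrPD/NoThickStrPD", -0.599),
    ("SeptalAGG/Septal", -1.782),
    ("StrLengthSD/StrWidthSD", -0.761),
    ("NoThinStrFA/NoThickStrFA", 0.957),
    ("NoThickStrFD/NoStrFD", -0.443),
    ("StrLengthFD/StrWidthFD", 1.067),
)
PUBLISHED_INTERCEPT = 3.838

#: default selection sizes per candidate pool
DEFAULT_K_MAX = {"combined": 18, "overlap": 8, "portal": 11, "septal": 11, "fibrillar": 13}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationParams:
    """Per-feature (min, max) learned from a training table."""

    mins: pd.Series
    maxs: pd.Series

    def __post_init__(self):
        if (self.maxs < self.mins).any():
            raise ValueError("normalization requires min <= max for every feature")


def fit_normalization(table: pd.DataFrame) -> NormalizationParams:
    _check_numeric(table)
    return NormalizationParams(table.min(axis=0), table.max(axis=0))


def apply_normalization(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """(x - min) / (max - min), clipped to [0, 1]; constant features map to 0."""
    _check_numeric(table)
    cols = params.mins.index
    span = (params.maxs - params.mins).replace(0.0, np.nan)
    out = (table[cols] - params.mins) / span
    out = out.fillna(0.0).clip(0.0, 1.0)
    return out


def _check_numeric(table: pd.DataFrame) -> None:
    bad = [c for c in table.columns if not np.issubdtype(table[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric columns: {bad}")
    if table.isna().any().any():
        raise ValueError("table contains missing values")


# ---------------------------------------------------------------------------
# ordinary least squares with explicit rank handling
# ---------------------------------------------------------------------------


def _ols(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Minimum-norm least squares; returns (beta, rss, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid), int(rank)


def sequential_forward_selection(
    X: pd.DataFrame,
    y: Sequence[float],
    k_max: int,
    pool: Sequence[str] | None = None,
    rss_improvement_tol: float | None = None,
) -> list[str]:
    """Greedy forward selection minimizing the linear-model RSS.

    At each step the candidate whose inclusion gives the smallest
    least-squares RSS is added; ties break toward the earlier candidate in
    pool (taxonomy) order.  Candidates that make the design rank deficient
    are skipped with a warning.  If ``rss_improvement_tol`` is set, selection
    stops early once the relative RSS improvement falls below it.
    """
    _check_numeric(X)
    y = np.asarray(y, dtype=float)
    if k_max < 0:
        raise ValueError("k_max must be nonnegative")
    if k_max >= len(X):
        raise ValueError("k_max must be smaller than the number of samples")
    candidates = [c for c in (pool if pool is not None else X.columns) if c in X.columns]

    selected: list[str] = []
    Xv = X[candidates].to_numpy(dtype=float)
    col_of = {name: i for i, name in enumerate(candidates)}
    n = len(X)
    design = np.ones((n, 1))
    prev_rss = float(np.sum((y - y.mean()) ** 2))

    for _ in range(k_max):
        best_name, best_rss = None, np.inf
        for name in candidates:
            if name in selected:
                continue
            A = np.column_stack([design, Xv[:, col_of[name]]])
            beta, rss, rank = _ols(A, y)
            if rank < A.shape[1]:
                warnings.warn(
                    f"feature {name!r} is collinear with the current selection; skipped"
                )
                continue
            if rss < best_rss - 1e-12:
                best_name, best_rss = name, rss
        if best_name is None:
            break
        if (
            rss_improvement_tol is not None
            and prev_rss > 0
            and (prev_rss - best_rss) / prev_rss < rss_improvement_tol
        ):
            break
        selected.append(best_name)
        design = np.column_stack([design, Xv[:, col_of[best_name]]])
        prev_rss = best_rss
    return selected


# ---------------------------------------------------------------------------
# linear index model
# ---------------------------------------------------------------------------


@dataclass
class LinearIndexModel:
    """A linear risk index: intercept + sum(coef * normalized feature).

    ``normalization=None`` means raw feature values are used unchanged (the
    shipped published model: its training min/max were never released, so it
    reproduces the printed arithmetic, not the study's per-patient indices).
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    normalization: NormalizationParams | None = None
    candidate_pool: str = "combined"

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficients and feature_names lengths differ")

    def score(self, features) -> float | np.ndarray:
        """Combined index for a feature vector (mapping/Series) or table."""
        if isinstance(features, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in features.columns]
            if missing:
                raise KeyError(f"missing model features: {missing}")
            X = features[self.feature_names]
            if self.normalization is not None and self.feature_names:
                sub = NormalizationParams(
                    self.normalization.mins[self.feature_names],
                    self.normalization.maxs[self.feature_names],
                )
                X = apply_normalization(X, sub)
            if not self.feature_names:
                return np.full(len(features), self.intercept)
            return self.intercept + X.to_numpy(dtype=float) @ self.coefficients
        if isinstance(features, pd.Series):
            features = features.to_dict()
        missing = [n for n in self.feature_names if n not in features]
        if missing:
            raise KeyError(f"missing model features: {missing}")
        row = pd.DataFrame([{n: features[n] for n in self.feature_names}])
        return float(self.score(row)[0])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "candidate_pool": self.candidate_pool,
            "normalization": None
            if self.normalization is None
            else {
                "mins": self.normalization.mins[self.feature_names].tolist(),
                "maxs": self.normalization.maxs[self.feature_names].tolist(),
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearIndexModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        norm = None
        if d["normalization"] is not None:
            idx = pd.Index(d["feature_names"])
            norm = NormalizationParams(
                pd.Series(d["normalization"]["mins"], index=idx),
                pd.Series(d["normalization"]["maxs"], index=idx),
            )
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            normalization=norm,
            candidate_pool=d.get("candidate_pool", "combined"),
        )


def fit_linear_index(
    X_selected: pd.DataFrame,
    y: Sequence[float],
    normalization: NormalizationParams | None = None,
    candidate_pool: str = "combined",
    on_singular: str = "warn",
) -> LinearIndexModel:
    """Ordinary least squares of the 0/1 label on the selected features."""
    _check_numeric(X_selected)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(X_selected)), X_selected.to_numpy(dtype=float)])
    beta, _, rank = _ols(A, y)
    if rank < A.shape[1]:
        # identify columns not adding rank, scanning left to right
        offenders = []
        r = 1
        for j, name in enumerate(X_selected.columns, start=1):
            rj = np.linalg.matrix_rank(A[:, : j + 1])
            if rj == r:
                offenders.append(name)
            r = rj
        msg = f"rank-deficient design; offending columns: {offenders}"
        if on_singular == "raise":
            raise ValueError(msg)
        warnings.warn(msg + "; using minimum-norm solution")
    return LinearIndexModel(
        feature_names=list(X_selected.columns),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        normalization=normalization,
        candidate_pool=candidate_pool,
    )


def published_combined_model() -> LinearIndexModel:
    """The shipped 18-feature model with the printed coefficients."""
    names = [n for n, _ in PUBLISHED_COEFFICIENTS]
    coefs = np.array([c for _, c in PUBLISHED_COEFFICIENTS])
    return LinearIndexModel(
        feature_names=names,
        coefficients=coefs,
        intercept=PUBLISHED_INTERCEPT,
        normalization=None,
        candidate_pool="combined",
    )


# ---------------------------------------------------------------------------
# risk threshold and scoring
# ---------------------------------------------------------------------------


@dataclass
class RiskThreshold:
    """Decision rule: index strictly greater than ``cutoff`` is high risk."""

    cutoff: float = PUBLISHED_CUTOFF

    def classify(self, index):
        return np.where(np.asarray(index) > self.cutoff, "high", "low")


def score_and_classify(
    features, model: LinearIndexModel, threshold: RiskThreshold | None = None
):
    """Return (combined index, risk label) for a vector or a table."""
    threshold = threshold or RiskThreshold()
    index = model.score(features)
    risk = threshold.classify(index)
    if np.isscalar(index):
        return index, str(risk)
    return index, risk


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class CombinedIndexRegressor(BaseEstimator, RegressorMixin):
    """Linear early-recurrence index with forward selection, sklearn style.

    Parameters
    ----------
    k_max : int or None
        Number of features to select; None picks the pool default
        (18 combined / 8 overlap / 11 portal / 11 septal / 13 fibrillar).
    pool : str
        Candidate pool: 'combined' or one of the region pools.
    taxonomy : FeatureTaxonomy or None
        Feature taxonomy used to resolve region pools and tie-break order;
        None restricts pools to the columns of X in their given order.
    rss_improvement_tol : float or None
        Optional early stop when the relative RSS improvement falls below it.

    Attributes (after fit)
    ----------------------
    normalization_ : NormalizationParams
    selected_features_ : list of str
    coef_ : ndarray, intercept_ : float
    model_ : LinearIndexModel
    """

    def __init__(
        self,
        k_max: int | None = None,
        pool: str = "combined",
        taxonomy: FeatureTaxonomy | None = DEFAULT_TAXONOMY,
        rss_improvement_tol: float | None = None,
    ):
        self.k_max = k_max
        self.pool = pool
        self.taxonomy = taxonomy
        self.rss_improvement_tol = rss_improvement_tol

    def _pool_names(self, columns) -> list[str]:
        if self.taxonomy is not None:
            return [n for n in self.taxonomy.pool(self.pool) if n in columns]
        return list(columns)

    def fit(self, X: pd.DataFrame, y):
        X = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        k = self.k_max if self.k_max is not None else DEFAULT_K_MAX[self.pool]
        self.normalization_ = fit_normalization(X)
        Xn = apply_normalization(X, self.normalization_)
        self.selected_features_ = sequential_forward_selection(
            Xn, y, k_max=k, pool=self._pool_names(X.columns),
            rss_improvement_tol=self.rss_improvement_tol,
        )
        self.model_ = fit_linear_index(
            Xn[self.selected_features_], y,
            normalization=self.normalization_, candidate_pool=self.pool,
        )
        self.coef_ = self.model_.coefficients
        self.intercept_ = self.model_.intercept
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = self._as_frame(X)
        return np.asarray(self.model_.score(X), dtype=float)

    def classify(self, X, threshold: RiskThreshold | None = None) -> np.ndarray:
        threshold = threshold or RiskThreshold()
        return threshold.classify(self.predict(X))

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class LoocvResult:
    """Per-sample held-out predictions plus fold bookkeeping."""

    predictions: np.ndarray
    n_folds: int
    selected_features: list[str] | None  # fixed_selection mode
    fold_selected: list[list[str]] = field(default_factory=list)  # nested mode
    fold_train_sizes: list[int] = field(default_factory=list)


def loocv_predict(
    table: pd.DataFrame,
    labels,
    k_max: int | None = None,
    pool: str = "combined",
    mode: str = "fixed_selection",
    taxonomy: FeatureTaxonomy | None = DEFAULT_TAXONOMY,
) -> LoocvResult:
    """Leave-one-out predictions of the combined index.

    ``fixed_selection`` (default) chooses the feature subset once on the full
    data and refits normalization + coefficients inside each fold, mirroring
    the published description; ``nested`` redoes selection per fold (the
    unbiased variant).
    """
    if mode not in ("fixed_selection", "nested"):
        raise ValueError("mode must be 'fixed_selection' or 'nested'")
    X = CombinedIndexRegressor._as_frame(table)
    y = np.asarray(labels, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 samples")
    k = k_max if k_max is not None else DEFAULT_K_MAX[pool]
    est = CombinedIndexRegressor(k_max=k, pool=pool, taxonomy=taxonomy)
    pool_names = est._pool_names(X.columns)

    fixed = None
    if mode == "fixed_selection":
        norm_full = fit_normalization(X)
        Xn_full = apply_normalization(X, norm_full)
        fixed = sequential_forward_selection(Xn_full, y, k_max=k, pool=pool_names)

    preds = np.empty(n)
    fold_selected: list[list[str]] = []
    fold_sizes: list[int] = []
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        X_tr, y_tr = X.iloc[train], y[train]
        norm = fit_normalization(X_tr)
        Xn_tr = apply_normalization(X_tr, norm)
        if mode == "nested":
            sel = sequential_forward_selection(Xn_tr, y_tr, k_max=k, pool=pool_names)
        else:
            sel = fixed
        fold_selected.append(list(sel))
        fold_sizes.append(int(train.sum()))
        model = fit_linear_index(Xn_tr[sel], y_tr, normalization=norm, candidate_pool=pool)
        preds[i] = model.score(X.iloc[[i]])[0]
    return LoocvResult(
        predictions=preds,
        n_folds=n,
        selected_features=fixed,
        fold_selected=fold_selected,
        fold_train_sizes=fold_sizes,
    )
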