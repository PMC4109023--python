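"""Partial least-squares models linking thrombus type to measured parameters
or to the binary receptor assignment matrix.

Thrombus type is coded ordinally (1, 2, 3) on a single numeric axis and
regressed by PLS (NIPALS, sequential component extraction on mean-centered
data; optional unit-variance scaling). From the assignment matrix — surfaces
× nine platelet receptors (GPIb-V-IX, GPVI, CLEC-2, α2β1, α5β1, α6β1, αIIbβ3,
αvβ3, CD36), entries 0/1 per shear condition — the regression coefficients
form a β-weight matrix attributing thrombus-type formation to individual
receptors; a negative weight only indicates a receptor's relative inability
to drive fully formed (type III) thrombi, not inhibition. Continuous
predictions are rounded half-up and clamped to 1–3, summarized in confusion
matrices, and every model can be checked by leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import RECEPTORS

__all__ = [
    "PLSModel",
    "BetaWeightMatrix",
    "ConfusionReport",
    "fit_pls",
    "predict",
    "predict_type",
    "confusion",
    "to_type",
    "crossval",
    "receptor_beta",
    "refit_lowshear",
    "subtraction_heatmap",
]


@dataclass
class PLSModel:
    """A fitted PLS1 regression model.

    ``coef`` maps raw (uncentered) predictors to the response together with
    ``intercept``; ``x_variance_explained`` holds the fraction of centered
    predictor variance captured by each component.
    """

    columns: list
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # columns × components (w vectors)
    x_loadings: np.ndarray  # columns × components (p vectors)
    y_loadings: np.ndarray  # components (q scalars)
    coef: np.ndarray
    intercept: float
    x_variance_explained: np.ndarray
    dropped_columns: list = field(default_factory=list)


@dataclass
class BetaWeightMatrix:
    """Intercept plus per-receptor PLS weights for thrombus-type prediction."""

    intercept: float
    weights: pd.Series
    shear: float | str | None
    n_surfaces: int
    n_components: int
    x_variance_explained: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        rows = [("(constant)", self.intercept)] + list(self.weights.items())
        return pd.DataFrame(rows, columns=["receptor", "beta"]).set_index("receptor")


@dataclass
class ConfusionReport:
    """3×3 confusion matrix of true × predicted thrombus type."""

    matrix: pd.DataFrame
    source: str = "fit"

    @property
    def misassigned(self) -> int:
        m = self.matrix.to_numpy()
        return int(m.sum() - np.trace(m))

    @property
    def per_class_errors(self) -> pd.Series:
        m = self.matrix
        return m.sum(axis=1) - pd.Series(np.diag(m), index=m.index)


def fit_pls(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    scale: bool = False,
) -> PLSModel:
    """Fit a PLS1 regression by NIPALS component extraction.

    Predictors are mean-centered (optionally scaled to unit variance); the
    response is centered. Each component takes the weight vector
    w ∝ Xᵀy, scores t = Xw, deflates X by t pᵀ and y by t q. Zero-variance
    predictor columns are dropped with a warning; asking for more components
    than the predictor rank is an error.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        cols = list(range(Xv.shape[1]))
    y = np.asarray(y, dtype=float)
    if np.isnan(Xv).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if n_components < 1:
        raise ValueError("n_components must be ≥ 1")

    col_sd = Xv.std(axis=0, ddof=1) if len(Xv) > 1 else np.zeros(Xv.shape[1])
    keep = col_sd > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance predictor columns: {dropped}", stacklevel=2)
        Xv = Xv[:, keep]
        cols = [c for c, k in zip(cols, keep) if k]
        col_sd = col_sd[keep]

    x_mean = Xv.mean(axis=0)
    Xc = Xv - x_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the predictor rank {rank}"
        )
    x_scale = col_sd if scale else np.ones(Xc.shape[1])
    Xc = Xc / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    total_x_var = float((Xc**2).sum())
    p_cols = Xc.shape[1]
    W = np.zeros((p_cols, n_components))
    P = np.zeros((p_cols, n_components))
    Q = np.zeros(n_components)
    xvar = np.zeros(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(
                f"component {a + 1}: residual predictors are uncorrelated with "
                "the residual response; reduce n_components"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        q = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W[:, a], P[:, a], Q[a] = w, p, q
        xvar[a] = tt * float(p @ p) / total_x_var if total_x_var > 0 else 0.0

    # B = W (PᵀW)⁻¹ q on the centered/scaled scale
    B = W @ np.linalg.solve(P.T @ W, Q)
    coef = B / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        columns=cols,
        n_components=n_components,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        coef=coef,
        intercept=intercept,
        x_variance_explained=xvar,
        dropped_columns=dropped,
    )


def _align(model: PLSModel, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.columns if c not in X.columns]
        if missing:
            raise ValueError(f"prediction input lacks columns {missing}")
        return X[model.columns].to_numpy(dtype=float)
    Xv = np.asarray(X, dtype=float)
    if Xv.shape[1] != len(model.columns):
        raise ValueError(
            f"expected {len(model.columns)} predictor columns, got {Xv.shape[1]}"
        )
    return Xv


def predict(model: PLSModel, X) -> np.ndarray:
    """Continuous response prediction."""
    return _align(model, X) @ model.coef + model.intercept


def to_type(values: np.ndarray) -> np.ndarray:
    """Round a (possibly continuous) response to thrombus types: nearest
    integer, half-up, clamped to [1, 3]."""
    return np.clip(np.floor(np.asarray(values, dtype=float) + 0.5), 1, 3).astype(int)


def predict_type(model: PLSModel, X) -> np.ndarray:
    """Predicted thrombus type: rounded to the nearest integer (half-up) and
    clamped to [1, 3]."""
    return to_type(predict(model, X))


def confusion(true, predicted, source: str = "fit") -> ConfusionReport:
    """3×3 confusion matrix of true vs predicted thrombus types."""
    t = np.asarray(true, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted must have equal length")
    if not (np.isin(t, (1, 2, 3)).all() and np.isin(p, (1, 2, 3)).all()):
        raise ValueError("thrombus type labels must lie in {1, 2, 3}")
    m = np.zeros((3, 3), dtype=int)
    for a, b in zip(t, p):
        m[a - 1, b - 1] += 1
    idx = pd.Index([1, 2, 3], name="true")
    cols = pd.Index([1, 2, 3], name="predicted")
    return ConfusionReport(matrix=pd.DataFrame(m, index=idx, columns=cols), source=source)


def crossval(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    scale: bool = False,
) -> tuple[ConfusionReport, np.ndarray]:
    """Leave-one-out cross-validated type predictions.

    Each surface is held out in turn, the model refitted on the rest (with
    its own centering/scaling), and the held-out type predicted. Returns the
    CV confusion report and the per-surface predictions.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 observations")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(Xv[keep], y[keep], n_components, scale=scale)
        row = Xv[i][[c for c in range(Xv.shape[1]) if c in model.columns]]
        preds[i] = predict_type(model, row[None, :])[0]
    report = confusion(to_type(y), preds, source="cross-validation")
    return report, preds


def receptor_beta(
    A: pd.DataFrame,
    y: np.ndarray,
    n_components: int = 3,
    *,
    shear: float | str | None = None,
    scale: bool = False,
    allow_zero_rows: bool = False,
) -> tuple[BetaWeightMatrix, ConfusionReport, PLSModel]:
    """β-weight matrix: per-receptor contribution to thrombus type.

    Fits PLS of the type codes on the binary assignment matrix and reports
    the intercept and one weight per receptor, together with the confusion
    matrix of the rounded in-sample predictions. All-zero (never engaged)
    receptor columns are dropped with a warning and carry no weight. A
    surface engaging no receptor is rejected unless ``allow_zero_rows`` is
    set (which a receptor-exclusion refit legitimately needs).
    """
    a = A.to_numpy()
    if not np.isin(a, (0, 1)).all():
        raise ValueError("assignment matrix must be binary")
    if not allow_zero_rows and (a.sum(axis=1) == 0).any():
        bad = A.index[a.sum(axis=1) == 0][0]
        raise ValueError(f"surface {bad!r} engages no receptor")
    try:
        model = fit_pls(A, np.asarray(y, dtype=float), n_components, scale=scale)
    except ValueError as err:
        if "exceeds the predictor rank" in str(err):
            rank = np.linalg.matrix_rank(a - a.mean(axis=0))
            raise ValueError(
                f"assignment matrix rank ({rank}) is below n_components="
                f"{n_components}; try n_components={rank}"
            ) from None
        raise
    beta = BetaWeightMatrix(
        intercept=model.intercept,
        weights=pd.Series(model.coef, index=model.columns, name="beta"),
        shear=shear,
        n_surfaces=len(A),
        n_components=n_components,
        x_variance_explained=model.x_variance_explained,
    )
    report = confusion(to_type(y), predict_type(model, A), source="fit")
    return beta, report, model


def refit_lowshear(
    low_A: pd.DataFrame,
    low_y: np.ndarray,
    *,
    n_components: int = 2,
    exclude_receptor: str | None = None,
    scale: bool = False,
) -> tuple[BetaWeightMatrix, ConfusionReport, PLSModel]:
    """Rebuild the receptor model on low-shear data.

    ``separate-scaled`` behaviour is the default: centering (and optional
    scaling) are recomputed on the low-shear surfaces alone. Passing
    ``exclude_receptor`` drops that receptor's column before refitting — the
    device used to remove the GPIb contribution, which is not expected to
    operate at venous shear.
    """
    if exclude_receptor is not None:
        if exclude_receptor not in low_A.columns:
            known = ", ".join(map(str, low_A.columns))
            raise ValueError(
                f"unknown receptor {exclude_receptor!r}; expected one of: {known}"
            )
        low_A = low_A.drop(columns=[exclude_receptor])
    return receptor_beta(
        low_A,
        low_y,
        n_components,
        shear="low",
        scale=scale,
        allow_zero_rows=exclude_receptor is not None,
    )


def subtraction_heatmap(
    matA: pd.DataFrame,
    matB: pd.DataFrame,
    replicatesA: pd.DataFrame,
    replicatesB: pd.DataFrame,
    *,
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cell difference A − B with two-sided t-tests.

    ``matA``/``matB`` are matched surface × parameter mean tables; the
    replicate tables are tidy (surface, parameter, run, value) and must hold
    at least 2 runs per cell on each side. Returns (difference, p-values,
    significance mask at ``alpha``); Student's pooled-variance t by default.
    """
    if list(matA.index) != list(matB.index) or list(matA.columns) != list(matB.columns):
        raise ValueError("A and B layouts (surfaces × parameters) must match")
    diff = matA - matB
    p = pd.DataFrame(np.nan, index=matA.index, columns=matA.columns)
    ga = replicatesA.groupby(["surface", "parameter"])["value"]
    gb = replicatesB.groupby(["surface", "parameter"])["value"]
    for s in matA.index:
        for c in matA.columns:
            va = ga.get_group((s, c)).to_numpy()
            vb = gb.get_group((s, c)).to_numpy()
            if len(va) < 2 or len(vb) < 2:
                raise ValueError(f"cell ({s!r}, {c!r}) has fewer than 2 replicates")
            res = stats.ttest_ind(va, vb, equal_var=not welch)
            p.loc[s, c] = res.pvalue
    return diff, p, p < alpha
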