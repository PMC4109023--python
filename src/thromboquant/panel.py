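"""Surface × parameter panels: replicate aggregation, 0–10 normalization,
intra/inter-individual variability, and per-parameter determination.

Raw per-run measurements arrive as a tidy table (surface, parameter, run,
value). Cell means over runs form the raw ParameterMatrix; each parameter is
then linearly rescaled across surfaces so its minimum maps to 0 and its
maximum to 10, putting all eight parameters on a common comparative scale.
Normalization bounds can be frozen and reapplied, so patient panels are
expressed on the healthy-control scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterMatrix",
    "VariabilityReport",
    "aggregate_replicates",
    "normalize_matrix",
    "apply_bounds",
    "compute_cv",
    "parameter_determination",
]


@dataclass
class ParameterMatrix:
    """Surfaces × parameters table with replicate provenance.

    ``values`` holds cell means over runs; ``normalized`` (if present) the
    0–10 rescaled values, with ``bounds`` recording the per-parameter (min,
    max) used so the same scale can be applied to new data.
    """

    values: pd.DataFrame
    sd: pd.DataFrame | None = None
    n_runs: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None
    bounds: dict[str, tuple[float, float]] | None = None
    shear: float | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("surface and parameter labels must be unique")


@dataclass
class VariabilityReport:
    """Per-parameter intra-/inter-individual CVs (%) and their ratio."""

    table: pd.DataFrame  # columns: intra_cv, inter_cv, ratio

    @property
    def pooled_ratio(self) -> float:
        """Cohort-level inter/intra ratio: mean inter CV over mean intra CV,
        pooled across parameters."""
        return float(self.table["inter_cv"].mean() / self.table["intra_cv"].mean())


def aggregate_replicates(runs: pd.DataFrame, shear: float | None = None) -> ParameterMatrix:
    """Aggregate a tidy per-run table into a raw ParameterMatrix.

    ``runs`` needs columns surface, parameter, run, value. Cell mean and
    sample s.d. (ddof=1; 0 with a single run) are computed over runs, and the
    replicate count recorded. Duplicate (surface, parameter, run) keys are an
    error — they indicate a mislabeled input, not extra replication.
    """
    required = {"surface", "parameter", "run", "value"}
    missing = required - set(runs.columns)
    if missing:
        raise ValueError(f"runs table lacks columns: {sorted(missing)}")
    if runs.duplicated(["surface", "parameter", "run"]).any():
        dup = runs[runs.duplicated(["surface", "parameter", "run"], keep=False)]
        raise ValueError(
            "duplicate (surface, parameter, run) keys, e.g. "
            f"{dup.iloc[0][['surface', 'parameter', 'run']].tolist()}"
        )
    if runs["value"].isna().any():
        bad = runs[runs["value"].isna()].iloc[0]
        raise ValueError(
            f"NaN value at surface={bad['surface']!r}, parameter={bad['parameter']!r}, "
            f"run={bad['run']!r}"
        )
    g = runs.groupby(["surface", "parameter"], sort=False)["value"]
    means = g.mean().unstack("parameter")
    sd = g.std(ddof=1).unstack("parameter").fillna(0.0)
    n = g.size().unstack("parameter")
    # preserve first-appearance order of labels
    surf_order = list(dict.fromkeys(runs["surface"]))
    param_order = list(dict.fromkeys(runs["parameter"]))
    means = means.reindex(index=surf_order, columns=param_order)
    return ParameterMatrix(
        values=means,
        sd=sd.reindex_like(means),
        n_runs=n.reindex_like(means),
        shear=shear,
    )


def _column_bounds(values: pd.DataFrame) -> dict[str, tuple[float, float]]:
    return {c: (float(values[c].min()), float(values[c].max())) for c in values.columns}


def apply_bounds(
    values: pd.DataFrame, bounds: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Rescale columns to 0–10 with frozen per-parameter (min, max) bounds.

    Values outside the bounds map outside [0, 10]; callers comparing patients
    against a healthy reference usually want that visible rather than clipped.
    Degenerate bounds (max == min) map the whole column to 0 with a warning.
    """
    out = {}
    for c in values.columns:
        lo, hi = bounds[c]
        if hi <= lo:
            warnings.warn(
                f"parameter {c!r} has no dynamic range (max == min); mapped to 0",
                stacklevel=2,
            )
            out[c] = pd.Series(0.0, index=values.index)
        else:
            out[c] = 10.0 * (values[c] - lo) / (hi - lo)
    return pd.DataFrame(out, index=values.index)


def normalize_matrix(m: ParameterMatrix) -> ParameterMatrix:
    """Linearly normalize each parameter to 0–10 across surfaces.

    Per parameter, x → 10·(x − min)/(max − min) over the surface panel. The
    bounds are stored on the returned matrix so they can be frozen and reused
    (e.g. for patient panels). The input is not modified.
    """
    if m.values.isna().any().any():
        cell = np.argwhere(m.values.isna().to_numpy())[0]
        raise ValueError(
            f"missing cell at surface={m.values.index[cell[0]]!r}, "
            f"parameter={m.values.columns[cell[1]]!r}"
        )
    bounds = _column_bounds(m.values)
    return ParameterMatrix(
        values=m.values,
        sd=m.sd,
        n_runs=m.n_runs,
        normalized=apply_bounds(m.values, bounds),
        bounds=bounds,
        shear=m.shear,
    )


def compute_cv(cohort: pd.DataFrame) -> VariabilityReport:
    """Intra- and inter-individual coefficients of variation per parameter.

    ``cohort`` is tidy: subject, day, surface, parameter, value. Per
    parameter, pooled over surfaces by unweighted averaging:

    - intra CV: for each subject × surface, s.d. over days / mean over days
      × 100, averaged over subjects and surfaces;
    - inter CV: for each surface, s.d. of subject means (over days) / grand
      mean × 100, averaged over surfaces;
    - ratio: inter / intra (NaN when intra is 0).
    """
    required = {"subject", "day", "surface", "parameter", "value"}
    if required - set(cohort.columns):
        raise ValueError(f"cohort table lacks columns: {sorted(required - set(cohort.columns))}")
    if cohort["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if cohort.groupby("subject")["day"].nunique().min() < 2:
        raise ValueError("need at least 2 days per subject")

    rows = {}
    for param, sub in cohort.groupby("parameter", sort=False):
        within = sub.groupby(["subject", "surface"])["value"]
        w_mean, w_sd = within.mean(), within.std(ddof=1)
        if (w_mean == 0).any():
            raise ValueError(f"zero within-subject mean for parameter {param!r}")
        intra = float((100.0 * w_sd / w_mean).mean())

        subj_means = (
            sub.groupby(["surface", "subject"])["value"].mean().unstack("subject")
        )
        grand = subj_means.mean(axis=1)
        if (grand == 0).any():
            raise ValueError(f"zero grand mean for parameter {param!r}")
        inter = float((100.0 * subj_means.std(axis=1, ddof=1) / grand).mean())
        rows[param] = {
            "intra_cv": intra,
            "inter_cv": inter,
            "ratio": inter / intra if intra > 0 else np.nan,
        }
    return VariabilityReport(table=pd.DataFrame(rows).T[["intra_cv", "inter_cv", "ratio"]])


def parameter_determination(
    normalized: pd.DataFrame, types: pd.Series | np.ndarray
) -> pd.DataFrame:
    """How strongly each parameter determines the thrombus type.

    Per parameter: R² and two-sided p-value of the simple linear regression of
    the type code (1/2/3) on that parameter across surfaces. A final
    ``joint`` row reports the multiple regression of type on all parameters
    together.
    """
    y = np.asarray(pd.Series(types).reindex(normalized.index) if isinstance(types, pd.Series) else types, dtype=float)
    if len(y) != len(normalized):
        raise ValueError("types must cover all surfaces")
    if len(normalized) < 3:
        raise ValueError("need at least 3 surfaces")
    rows = {}
    for c in normalized.columns:
        res = stats.linregress(normalized[c].to_numpy(), y)
        rows[c] = {"r2": res.rvalue**2, "p": res.pvalue}
    X = np.column_stack([np.ones(len(y)), normalized.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    k = normalized.shape[1]
    dof = len(y) - k - 1
    if ss_tot > 0 and dof > 0:
        r2 = 1.0 - ss_res / ss_tot
        f = (r2 / k) / ((1 - r2) / dof) if r2 < 1 else np.inf
        p = float(stats.f.sf(f, k, dof))
    else:
        r2, p = np.nan, np.nan
    rows["joint"] = {"r2": r2, "p": p}
    return pd.DataFrame(rows).T[["r2", "p"]]
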