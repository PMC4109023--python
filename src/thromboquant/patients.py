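"""Patient deviation profiling against healthy-control reference ranges.

A patient's surface × parameter panel is compared with reference ranges built
from ≥2 healthy controls: per-cell subtraction heatmaps with two-sided
t-tests, and a significance map flagging cells outside the healthy mean ± 2
between-subject s.d. (−1 below, +1 above), with a per-patient tally of
reduced and increased parameters. No multiple-testing correction is applied
by default, matching the per-cell α = 0.05 presentation; Benjamini–Hochberg
is available as an opt-in extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceRange",
    "SignificanceMap",
    "reference_ranges",
    "significance_map",
    "patient_subtraction",
    "deviation_summary",
]


@dataclass
class ReferenceRange:
    """Per surface × parameter healthy-control mean, between-subject s.d.,
    and subject count. Cells with a single subject carry NaN s.d. and are
    untestable in the significance map."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    n: pd.DataFrame
    bounds: dict | None = None  # frozen 0–10 normalization bounds, if any


@dataclass
class SignificanceMap:
    """Per-cell flags: −1 (< mean − m·s.d.), +1 (> mean + m·s.d.), 0 inside,
    NaN untestable. Counts tally the testable cells only."""

    flags: pd.DataFrame
    sd_multiplier: float
    subject: str = "patient"

    @property
    def n_reduced(self) -> int:
        return int((self.flags == -1).sum().sum())

    @property
    def n_increased(self) -> int:
        return int((self.flags == 1).sum().sum())

    @property
    def n_tested(self) -> int:
        return int(self.flags.notna().sum().sum())


def reference_ranges(controls: pd.DataFrame) -> ReferenceRange:
    """Healthy reference ranges from a tidy control cohort table.

    ``controls`` has columns subject, day (or run), surface, parameter,
    value. Each subject is first aggregated to its mean per cell; the
    reference mean and s.d. are then taken across subjects, so the s.d. is
    the between-subject (inter-individual) spread a patient should be judged
    against.
    """
    required = {"subject", "surface", "parameter", "value"}
    if required - set(controls.columns):
        raise ValueError(
            f"control table lacks columns: {sorted(required - set(controls.columns))}"
        )
    if controls["subject"].nunique() < 2:
        raise ValueError("need at least 2 control subjects")
    subj = (
        controls.groupby(["surface", "parameter", "subject"])["value"]
        .mean()
        .unstack("subject")
    )
    mean = subj.mean(axis=1).unstack("parameter")
    sd = subj.std(axis=1, ddof=1).unstack("parameter")
    n = subj.notna().sum(axis=1).unstack("parameter")
    sd = sd.where(n >= 2)  # single-subject cells: s.d. unavailable
    # restore first-appearance ordering
    s_order = list(dict.fromkeys(controls["surface"]))
    p_order = list(dict.fromkeys(controls["parameter"]))
    return ReferenceRange(
        mean=mean.reindex(index=s_order, columns=p_order),
        sd=sd.reindex(index=s_order, columns=p_order),
        n=n.reindex(index=s_order, columns=p_order),
    )


def _patient_grid(patient: pd.DataFrame, ref: ReferenceRange) -> pd.DataFrame:
    if isinstance(patient, pd.DataFrame) and {"surface", "parameter", "value"} <= set(
        patient.columns
    ):
        grid = patient.pivot_table(
            index="surface", columns="parameter", values="value", aggfunc="mean"
        )
        grid = grid.reindex(index=ref.mean.index, columns=ref.mean.columns)
    else:
        grid = patient
    if list(grid.index) != list(ref.mean.index) or list(grid.columns) != list(
        ref.mean.columns
    ):
        raise ValueError("patient layout does not match the reference layout")
    if grid.isna().any().any():
        raise ValueError("patient panel has cells missing from the reference layout")
    return grid


def significance_map(
    patient: pd.DataFrame,
    ref: ReferenceRange,
    sd_multiplier: float = 2.0,
    subject: str = "patient",
) -> SignificanceMap:
    """Flag patient cells outside the healthy mean ± ``sd_multiplier`` s.d.

    The comparison uses the between-subject s.d. of the reference, so a flag
    means the patient falls outside the healthy population range, not outside
    a single control's repeat variability. Cells whose reference s.d. is
    unavailable are NaN (untestable) and excluded from counts.
    """
    grid = _patient_grid(patient, ref)
    lo = ref.mean - sd_multiplier * ref.sd
    hi = ref.mean + sd_multiplier * ref.sd
    flags = pd.DataFrame(0.0, index=grid.index, columns=grid.columns)
    flags = flags.mask(grid.lt(lo), -1.0).mask(grid.gt(hi), 1.0)
    flags = flags.where(ref.sd.notna())
    return SignificanceMap(flags=flags, sd_multiplier=sd_multiplier, subject=subject)


def patient_subtraction(
    patient_runs: pd.DataFrame,
    control_runs: pd.DataFrame,
    *,
    alpha: float = 0.05,
    welch: bool = False,
    fdr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Patient − control difference heatmap with per-cell two-sided t-tests.

    Both inputs are tidy replicate tables; controls need a ``subject`` column
    (subjects are first collapsed to their per-cell means, the replication
    unit for the test), patients a ``run`` column. Cells with fewer than 2
    replicates on either side are untestable (NaN p). Returns (difference,
    p-values, significant mask at ``alpha``); set ``fdr=True`` for an
    optional Benjamini–Hochberg adjusted mask.
    """
    pcells = {
        k: g.to_numpy() for k, g in patient_runs.groupby(["surface", "parameter"])["value"]
    }
    subj_means = (
        control_runs.groupby(["subject", "surface", "parameter"])["value"]
        .mean()
        .reset_index()
    )
    ccells = {
        k: g.to_numpy() for k, g in subj_means.groupby(["surface", "parameter"])["value"]
    }
    if set(pcells) != set(ccells):
        raise ValueError("patient and control layouts do not match")
    s_order = list(dict.fromkeys(patient_runs["surface"]))
    p_order = list(dict.fromkeys(patient_runs["parameter"]))
    diff = pd.DataFrame(np.nan, index=s_order, columns=p_order)
    p = diff.copy()
    for s in s_order:
        for c in p_order:
            va, vb = pcells[(s, c)], ccells[(s, c)]
            diff.loc[s, c] = va.mean() - vb.mean()
            if len(va) >= 2 and len(vb) >= 2:
                p.loc[s, c] = stats.ttest_ind(va, vb, equal_var=not welch).pvalue
    if fdr:
        flat = p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
        mask = pd.DataFrame(
            adj.reshape(p.shape) < alpha, index=p.index, columns=p.columns
        )
    else:
        mask = p < alpha
    return diff, p, mask


def deviation_summary(m: SignificanceMap | pd.DataFrame) -> dict[str, int]:
    """Tally of reduced / increased / tested cells for one patient."""
    if isinstance(m, SignificanceMap):
        return {
            "reduced": m.n_reduced,
            "increased": m.n_increased,
            "tested": m.n_tested,
        }
    flags = m
    return {
        "reduced": int((flags == -1).sum().sum()),
        "increased": int((flags == 1).sum().sum()),
        "tested": int(flags.notna().sum().sum()),
    }
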