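"""Synthetic data generation with recorded ground truth.

Every downstream stage of the pipeline — image quantification, parameter-matrix
assembly, clustering, receptor modelling and patient profiling — can be
exercised on data produced here, with the generating truth stored alongside so
that recovery can be checked exactly.

Generators are pure functions of their arguments plus a mandatory integer
seed: the same call yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import label as _cc_label

__all__ = [
    "PARAMETERS",
    "RECEPTORS",
    "SyntheticScene",
    "SyntheticSeries",
    "SyntheticStack",
    "PlantedMatrixTruth",
    "PlantedReceptorTruth",
    "ReceptorDesign",
    "CohortTruth",
    "InfeasiblePackingError",
    "gen_scene",
    "gen_series",
    "gen_stack",
    "gen_parameter_matrix",
    "gen_receptor_design",
    "gen_cohort",
    "planted_matrix_truth",
    "planted_receptor_truth",
    "cohort_truth",
    "save_scene",
    "save_series",
    "save_stack",
]

#: The eight image-derived thrombus-formation parameters, in canonical order.
PARAMETERS = (
    "morphological_score",
    "integrated_feature_size",
    "platelet_deposition",
    "stable_adhesion",
    "fibrinogen_binding",
    "pselectin_expression",
    "thrombus_volume",
    "procoagulant_activity",
)

#: The nine platelet adhesion/signalling receptors of the assignment matrix.
RECEPTORS = (
    "GPIb-V-IX",
    "GPVI",
    "CLEC-2",
    "a2b1",
    "a5b1",
    "a6b1",
    "aIIbb3",
    "avb3",
    "CD36",
)

# Default rendering levels on the 8-bit scale; chosen so that the default
# segmentation pipeline recovers the truth mask exactly on noise-free scenes.
FOREGROUND_LEVEL = 80
BACKGROUND_LEVEL = 20
DEFAULT_NOISE_SD = 5.0
#: Default pixel size in μm (106 μm field over 512 px).
DEFAULT_PIXEL_SIZE = 106.0 / 512.0


class InfeasiblePackingError(RuntimeError):
    """Requested features could not be placed without overlap within budget."""


@dataclass
class SyntheticScene:
    """A single microscopy field of adhered platelets with known truth.

    ``truth_features`` are the connected-component areas of ``truth_mask``
    (pixels); ``truth_coverage`` is their total divided by the field size.
    """

    pixel_grid: np.ndarray
    truth_mask: np.ndarray
    truth_features: list[int]
    truth_coverage: float
    pixel_size: float
    seed: int


@dataclass
class SyntheticSeries:
    """Time series of a scene with a stable and a transient pixel population."""

    frames: list[np.ndarray]
    frame_interval: float
    stable_mask: np.ndarray
    #: (flat pixel indices, appear frame, disappear frame) per transient feature
    transient_events: list[tuple[np.ndarray, int, int]]
    seed: int


@dataclass
class SyntheticStack:
    """Confocal z-stack with a known per-pixel occupied height.

    Occupied voxels form a contiguous run from the bottom slice in every
    pixel column, so ``truth_volume_per_area`` (μm³/μm²) equals the mean of
    ``truth_height_map`` (μm).
    """

    slices: list[np.ndarray]
    slice_spacing: float
    truth_height_map: np.ndarray
    truth_volume_per_area: float
    pixel_size: float
    seed: int


@dataclass
class PlantedMatrixTruth:
    """Ground truth for a surface × parameter matrix with planted types."""

    surface_ids: list[str]
    true_type: np.ndarray  # per surface, in {1, 2, 3}
    type_mean_vectors: pd.DataFrame  # index 1..3, columns = parameters
    noise_sd: np.ndarray  # per parameter
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        overall = self.type_mean_vectors.mean(axis=1)
        if not (overall.is_monotonic_increasing and overall.is_unique):
            raise ValueError(
                "type mean vectors must have strictly increasing overall activation "
                "(type III > type II > type I)"
            )
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PlantedReceptorTruth:
    """Ground truth for a binary receptor design with a planted linear model."""

    assignment_rows: pd.DataFrame | None  # surfaces × receptors in {0,1}, or None to sample
    beta_true: np.ndarray  # intercept followed by one weight per receptor
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.assignment_rows is not None:
            a = self.assignment_rows.to_numpy()
            if not np.isin(a, (0, 1)).all():
                raise ValueError("assignment matrix must be binary")
            if (a.sum(axis=1) == 0).any():
                raise ValueError("every surface must engage at least one receptor")


@dataclass
class ReceptorDesign:
    """Sampled receptor design: assignment matrix, response, and noise draws.

    ``response = intercept + assignment · beta + noise``, clamped to [1, 3],
    so the stored pieces reconstruct the response exactly.
    """

    assignment: pd.DataFrame
    response: np.ndarray
    noise: np.ndarray
    truth: PlantedReceptorTruth


@dataclass
class CohortTruth:
    """Two-level variance model for healthy-control cohorts and one patient.

    A control observation is cell mean + subject effect (inter-individual sd)
    + day effect (intra-individual sd). The patient's planted value is cell
    mean + ``patient_shift`` × inter-individual sd, exactly.
    """

    cell_means: pd.DataFrame  # surfaces × parameters
    inter_sd: float
    intra_sd: float
    n_controls: int
    n_days: int
    patient_shift: pd.DataFrame  # same layout, units of inter_sd
    seed: int

    def __post_init__(self) -> None:
        if self.inter_sd < 0 or self.intra_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_controls < 2:
            raise ValueError("need at least 2 control subjects")
        if self.n_days < 1:
            raise ValueError("need at least 1 day per subject")
        if list(self.patient_shift.index) != list(self.cell_means.index) or list(
            self.patient_shift.columns
        ) != list(self.cell_means.columns):
            raise ValueError("patient_shift layout must match cell_means")


# ---------------------------------------------------------------------------
# scene / series / stack generators
# ---------------------------------------------------------------------------


def _render(mask: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    img = np.where(mask, float(FOREGROUND_LEVEL), float(BACKGROUND_LEVEL))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=mask.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _free_origins(grid: np.ndarray, H: int, W: int) -> np.ndarray:
    """Top-left corners of all H×W windows that contain no occupied pixel,
    via an integral image (exact, so packing fails only when impossible)."""
    if H > grid.shape[0] or W > grid.shape[1]:
        return np.empty((0, 2), dtype=int)
    ii = np.zeros((grid.shape[0] + 1, grid.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = grid.cumsum(axis=0).cumsum(axis=1)
    sums = ii[H:, W:] - ii[:-H, W:] - ii[H:, :-W] + ii[:-H, :-W]
    return np.argwhere(sums == 0)


def _rect_dims(area: float, rng: np.random.Generator) -> tuple[int, int]:
    aspect = rng.uniform(0.5, 2.0)
    w = max(3, int(round(np.sqrt(area * aspect))))
    h = max(3, int(round(area / w)))
    return h, w


def _ellipse_patch(area: float, rng: np.random.Generator) -> np.ndarray:
    aspect = rng.uniform(0.5, 2.0)
    b = max(1.5, np.sqrt(area / (np.pi * aspect)))
    a = max(1.5, area / (np.pi * b))
    ry, rx = int(np.ceil(a)), int(np.ceil(b))
    yy, xx = np.mgrid[-ry : ry + 1, -rx : rx + 1]
    return (yy / a) ** 2 + (xx / b) ** 2 <= 1.0


def gen_scene(
    n_features: int,
    *,
    seed: int,
    shape: tuple[int, int] = (512, 512),
    mean_area: float = 100.0,
    area_sigma: float = 0.6,
    areas: list[float] | None = None,
    feature_shape: str = "rectangle",
    noise_sd: float = DEFAULT_NOISE_SD,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    overlap: str = "none",
    max_tries: int = 10_000,
) -> SyntheticScene:
    """Generate one platelet-field scene with known feature areas and coverage.

    Feature areas are drawn from a lognormal (median ``mean_area`` px, shape
    ``area_sigma``) unless ``areas`` is given explicitly. Features are
    axis-aligned rectangles (default; minimum side 3 px) or ellipses, placed
    by rejection sampling with a 3-px clearance so each one stays a separate
    connected component. ``overlap='aggregate'`` drops the clearance and
    records the merged component areas as truth instead.
    """
    rng = np.random.default_rng(seed)
    grid = np.zeros(shape, dtype=bool)
    if feature_shape not in ("rectangle", "ellipse"):
        raise ValueError(f"unknown feature_shape {feature_shape!r}")
    if overlap not in ("none", "aggregate"):
        raise ValueError(f"unknown overlap policy {overlap!r}")

    if areas is None:
        sampled = rng.lognormal(np.log(mean_area), area_sigma, size=n_features)
    else:
        sampled = np.asarray(areas, dtype=float)
        if len(sampled) != n_features:
            raise ValueError("len(areas) must equal n_features")
    if sampled.sum() > 0.7 * grid.size:
        raise InfeasiblePackingError(
            f"requested foreground {sampled.sum():.0f} px exceeds 70% of the "
            f"{grid.size}-px grid"
        )

    margin = 3 if overlap == "none" else 0
    placed_areas: list[int] = []
    n_aspects = max(1, max_tries // 500)
    for target in sampled:
        placed = False
        for _aspect_try in range(n_aspects):
            # resample the aspect ratio so elongated draws cannot wedge packing
            if feature_shape == "rectangle":
                h, w = _rect_dims(target, rng)
                patch = np.ones((h, w), dtype=bool)
            else:
                patch = _ellipse_patch(target, rng)
                h, w = patch.shape
            if h + 2 * margin > shape[0] or w + 2 * margin > shape[1]:
                raise InfeasiblePackingError(
                    f"feature of {target:.0f} px does not fit the {shape} grid"
                )
            if overlap == "aggregate":
                r = int(rng.integers(margin, shape[0] - h - margin + 1))
                c = int(rng.integers(margin, shape[1] - w - margin + 1))
            else:
                # uniform draw over exactly the clearance-respecting origins
                origins = _free_origins(grid, h + 2 * margin, w + 2 * margin)
                if len(origins) == 0:
                    continue
                r, c = origins[int(rng.integers(len(origins)))] + margin
            grid[r : r + h, c : c + w] |= patch
            placed_areas.append(int(patch.sum()))
            placed = True
            break
        if not placed:
            raise InfeasiblePackingError(
                f"could not place a {target:.0f}-px feature without overlap "
                f"(grid {shape}, {len(placed_areas)} features already placed)"
            )

    # Truth always recomputed from the emitted mask so the conservation
    # invariants hold by construction, also in aggregate mode.
    labelled = _cc_label(grid, connectivity=2)
    truth_features = sorted(
        int(a) for a in np.bincount(labelled.ravel())[1:] if a > 0
    )
    return SyntheticScene(
        pixel_grid=_render(grid, noise_sd, rng),
        truth_mask=grid,
        truth_features=truth_features,
        truth_coverage=float(sum(truth_features)) / grid.size,
        pixel_size=pixel_size,
        seed=seed,
    )


def gen_series(
    scene: SyntheticScene,
    stable_fraction: float,
    *,
    seed: int,
    duration_s: float = 60.0,
    interval_s: float = 2.0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SyntheticSeries:
    """Turn a scene into a time series with a stable and a transient population.

    A subset of features persists in every frame (chosen greedily so the
    persisting pixel fraction matches ``stable_fraction`` to within one
    feature's granularity); each remaining feature is visible only during a
    random sub-window of frames.
    """
    if not 0.0 <= stable_fraction <= 1.0:
        raise ValueError("stable_fraction must lie in [0, 1]")
    n_frames_f = duration_s / interval_s
    if abs(n_frames_f - round(n_frames_f)) > 1e-9:
        raise ValueError(
            f"duration {duration_s}s is not a multiple of the interval {interval_s}s"
        )
    n_frames = int(round(n_frames_f))
    if n_frames < 2:
        raise ValueError("series needs at least 2 frames")

    rng = np.random.default_rng(seed)
    labelled = _cc_label(scene.truth_mask, connectivity=2)
    n_feat = labelled.max()
    order = rng.permutation(n_feat) + 1
    areas = np.bincount(labelled.ravel())
    total = areas[1:].sum()

    stable_ids: list[int] = []
    if stable_fraction >= 1.0:
        stable_ids = list(order)
    elif total > 0 and stable_fraction > 0.0:
        target = stable_fraction * total
        acc = 0
        for fid in order:
            if acc >= target:
                break
            # take the feature only if it brings us closer to the target
            if abs(acc + areas[fid] - target) <= abs(acc - target):
                stable_ids.append(int(fid))
                acc += areas[fid]

    stable_mask = np.isin(labelled, stable_ids) & scene.truth_mask
    transient_ids = [int(f) for f in order if f not in set(stable_ids)]

    events: list[tuple[np.ndarray, int, int]] = []
    for fid in transient_ids:
        appear = int(rng.integers(0, n_frames))
        disappear = int(rng.integers(appear + 1, n_frames + 1))
        if appear == 0 and disappear == n_frames:  # must vanish in ≥1 frame
            if rng.random() < 0.5:
                appear = 1
            else:
                disappear = n_frames - 1 if n_frames > 1 else n_frames
        idx = np.flatnonzero((labelled == fid).ravel())
        events.append((idx, appear, disappear))

    frames = []
    for t in range(n_frames):
        mask = stable_mask.copy()
        flat = mask.ravel()
        for idx, a, d in events:
            if a <= t < d:
                flat[idx] = True
        frames.append(_render(mask, noise_sd, rng))
    return SyntheticSeries(
        frames=frames,
        frame_interval=interval_s,
        stable_mask=stable_mask,
        transient_events=events,
        seed=seed,
    )


def gen_stack(
    *,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    n_slices: int = 12,
    slice_spacing: float = 0.5,
    n_features: int = 12,
    mean_area: float = 400.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> SyntheticStack:
    """Generate a confocal z-stack of thrombi with a known height map.

    Thrombus footprints come from :func:`gen_scene`; each footprint pixel gets
    an occupied height of 1..``n_slices`` slices, contiguous from the bottom.
    """
    scene = gen_scene(
        n_features,
        seed=seed,
        shape=shape,
        mean_area=mean_area,
        noise_sd=0.0,
        pixel_size=pixel_size,
    )
    rng = np.random.default_rng(seed + 1)
    h_slices = np.zeros(shape, dtype=int)
    fg = scene.truth_mask
    h_slices[fg] = rng.integers(1, n_slices + 1, size=int(fg.sum()))
    slices = [
        _render(h_slices > i, noise_sd, rng) for i in range(n_slices)
    ]
    height_map = h_slices * slice_spacing
    return SyntheticStack(
        slices=slices,
        slice_spacing=slice_spacing,
        truth_height_map=height_map,
        truth_volume_per_area=float(height_map.mean()),
        pixel_size=pixel_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# planted matrices, receptor designs, cohorts
# ---------------------------------------------------------------------------


def planted_matrix_truth(
    *,
    seed: int,
    n_surfaces: int = 52,
    parameters: tuple[str, ...] = PARAMETERS,
    separation: float = 4.0,
    noise_sd: float = 0.75,
    n_replicates: int = 3,
) -> PlantedMatrixTruth:
    """Default planted truth: three thrombus types at ``separation`` × noise sd.

    Type mean vectors sit at overall activation levels 2, 2+Δ, 2+2Δ with
    Δ = separation × noise_sd, plus a small fixed per-parameter offset so
    parameters are not exact copies of one another. With noise_sd = 0 the
    spacing falls back to Δ = 2 so the three types stay distinct.
    """
    rng = np.random.default_rng(seed)
    p = len(parameters)
    spread = noise_sd if noise_sd > 0 else 0.5
    delta = separation * spread
    jitter = rng.uniform(-0.2, 0.2, size=(3, p)) * spread
    base = 2.0 + delta * np.arange(3)[:, None]
    means = pd.DataFrame(base + jitter, index=[1, 2, 3], columns=list(parameters))
    # even-ish type assignment, shuffled
    types = np.asarray([1 + i % 3 for i in range(n_surfaces)])
    rng.shuffle(types)
    ids = [f"S{i + 1:02d}" for i in range(n_surfaces)]
    return PlantedMatrixTruth(
        surface_ids=ids,
        true_type=types,
        type_mean_vectors=means,
        noise_sd=np.full(p, noise_sd),
        n_replicates=n_replicates,
        seed=seed,
    )


def gen_parameter_matrix(
    truth: PlantedMatrixTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw replicate measurements around the planted type means.

    Returns ``(means, replicates)``: a surfaces × parameters table of replicate
    means, and a tidy replicate table (surface, parameter, run, value).
    """
    counts = np.bincount(truth.true_type, minlength=4)[1:]
    if (counts < 2).any():
        raise ValueError("need at least 2 surfaces per planted type")
    if truth.n_replicates < 2:
        raise ValueError("replicate-level output needs at least 2 replicates")
    rng = np.random.default_rng(truth.seed)
    params = list(truth.type_mean_vectors.columns)
    sd = np.asarray(truth.noise_sd, dtype=float)
    rows = []
    values = np.empty((len(truth.surface_ids), len(params)))
    for i, (sid, t) in enumerate(zip(truth.surface_ids, truth.true_type)):
        mu = truth.type_mean_vectors.loc[t].to_numpy()
        reps = mu + rng.normal(0.0, 1.0, size=(truth.n_replicates, len(params))) * sd
        values[i] = reps.mean(axis=0)
        for r in range(truth.n_replicates):
            for j, pname in enumerate(params):
                rows.append((sid, pname, r + 1, reps[r, j]))
    means = pd.DataFrame(values, index=truth.surface_ids, columns=params)
    means.index.name = "surface"
    reps_df = pd.DataFrame(rows, columns=["surface", "parameter", "run", "value"])
    return means, reps_df


def planted_receptor_truth(
    *,
    seed: int,
    noise_sd: float = 0.1,
    beta_true: np.ndarray | None = None,
) -> PlantedReceptorTruth:
    """Planted receptor model with a field-plausible weight pattern.

    Defaults plant strong positive weights on GPIb-V-IX, GPVI, CLEC-2, α6β1
    and αIIbβ3, a modest α2β1 weight, and small/negative weights on α5β1,
    αvβ3 and CD36, echoing the receptor hierarchy for fully formed
    (type III) thrombi. All planted weights are distinct and non-zero.
    """
    if beta_true is None:
        beta_true = np.array(
            [1.003, 0.543, 0.436, 0.542, 0.218, -0.114, 0.465, 0.446, -0.106, 0.113]
        )
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_true.shape != (len(RECEPTORS) + 1,):
        raise ValueError(
            f"beta_true must hold an intercept plus {len(RECEPTORS)} weights"
        )
    return PlantedReceptorTruth(
        assignment_rows=None, beta_true=beta_true, noise_sd=noise_sd, seed=seed
    )


def gen_receptor_design(
    truth: PlantedReceptorTruth,
    n_surfaces: int = 52,
    *,
    round_response: bool = False,
) -> ReceptorDesign:
    """Sample a binary assignment matrix and the planted linear response.

    response = intercept + A·β + ε, clamped to [1, 3]; ε draws are returned so
    the response is reconstructible from the stored pieces.

    Sampled surfaces mimic single- to quintuple-coated microspots: each row
    engages 1–5 receptors. Rows whose noise-free response would fall outside
    [1, 3] are resampled, so the planted linear model itself respects the
    three-class coding range and clamping only ever acts on the noise.
    Explicitly supplied assignment rows are used as-is.
    """
    n_rec = len(truth.beta_true) - 1
    rng = np.random.default_rng(truth.seed)
    if truth.assignment_rows is not None:
        A = truth.assignment_rows.copy()
        if A.shape[1] != n_rec:
            raise ValueError("receptor count does not match beta_true length")
    else:
        b0, bw = truth.beta_true[0], truth.beta_true[1:]
        rows = np.zeros((n_surfaces, n_rec), dtype=int)
        for i in range(n_surfaces):
            for _try in range(10_000):
                k = int(rng.integers(1, 6))
                row = np.zeros(n_rec, dtype=int)
                row[rng.choice(n_rec, size=k, replace=False)] = 1
                if 1.0 <= b0 + row @ bw <= 3.0:
                    rows[i] = row
                    break
            else:
                raise ValueError(
                    "could not sample an assignment row with a noise-free "
                    "response inside [1, 3]; check beta_true"
                )
        A = pd.DataFrame(
            rows,
            index=[f"S{i + 1:02d}" for i in range(n_surfaces)],
            columns=list(RECEPTORS)[:n_rec],
        )
        A.index.name = "surface"
    eps = rng.normal(0.0, truth.noise_sd, size=len(A)) if truth.noise_sd > 0 else np.zeros(len(A))
    y = truth.beta_true[0] + A.to_numpy() @ truth.beta_true[1:] + eps
    y = np.clip(y, 1.0, 3.0)
    if round_response:
        y = np.clip(np.floor(y + 0.5), 1, 3)
    return ReceptorDesign(assignment=A, response=y, noise=eps, truth=truth)


def cohort_truth(
    *,
    seed: int,
    n_surfaces: int = 9,
    parameters: tuple[str, ...] = PARAMETERS[:6],
    n_controls: int = 6,
    n_days: int = 4,
    inter_sd: float = 0.9,
    intra_sd: float = 0.3,
    patient_shift: pd.DataFrame | None = None,
) -> CohortTruth:
    """Default healthy-reference cohort truth: a 9-surface × 6-parameter panel,
    6 subjects sampled on 4 days each, inter-individual spread 3× the
    day-to-day spread."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:02d}" for i in range(n_surfaces)]
    means = pd.DataFrame(
        rng.uniform(4.0, 8.0, size=(n_surfaces, len(parameters))),
        index=ids,
        columns=list(parameters),
    )
    means.index.name = "surface"
    if patient_shift is None:
        patient_shift = pd.DataFrame(0.0, index=ids, columns=list(parameters))
    return CohortTruth(
        cell_means=means,
        inter_sd=inter_sd,
        intra_sd=intra_sd,
        n_controls=n_controls,
        n_days=n_days,
        patient_shift=patient_shift,
        seed=seed,
    )


def gen_cohort(truth: CohortTruth) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample a control cohort and one patient from the two-level model.

    Returns ``(controls, patient, patient_runs)``:

    - ``controls``: tidy table (subject, day, surface, parameter, value) with
      value = cell mean + subject effect (inter sd) + day effect (intra sd);
    - ``patient``: tidy table (surface, parameter, value) holding the exact
      planted value, cell mean + shift × inter sd, without measurement noise;
    - ``patient_runs``: tidy replicate table (run, surface, parameter, value)
      with day-level noise around the planted value, ``n_days`` runs.
    """
    rng = np.random.default_rng(truth.seed)
    surfaces = list(truth.cell_means.index)
    params = list(truth.cell_means.columns)
    mu = truth.cell_means.to_numpy()
    ns, np_ = mu.shape

    rows = []
    for subj in range(truth.n_controls):
        subj_eff = rng.normal(0.0, truth.inter_sd, size=(ns, np_)) if truth.inter_sd > 0 else np.zeros((ns, np_))
        for day in range(truth.n_days):
            day_eff = rng.normal(0.0, truth.intra_sd, size=(ns, np_)) if truth.intra_sd > 0 else np.zeros((ns, np_))
            vals = mu + subj_eff + day_eff
            for i, s in enumerate(surfaces):
                for j, p in enumerate(params):
                    rows.append((f"C{subj + 1:02d}", day + 1, s, p, vals[i, j]))
    controls = pd.DataFrame(
        rows, columns=["subject", "day", "surface", "parameter", "value"]
    )

    planted = mu + truth.patient_shift.to_numpy() * truth.inter_sd
    patient = pd.DataFrame(
        [
            (s, p, planted[i, j])
            for i, s in enumerate(surfaces)
            for j, p in enumerate(params)
        ],
        columns=["surface", "parameter", "value"],
    )

    prows = []
    for run in range(truth.n_days):
        noise = rng.normal(0.0, truth.intra_sd, size=(ns, np_)) if truth.intra_sd > 0 else np.zeros((ns, np_))
        vals = planted + noise
        for i, s in enumerate(surfaces):
            for j, p in enumerate(params):
                prows.append((run + 1, s, p, vals[i, j]))
    patient_runs = pd.DataFrame(
        prows, columns=["run", "surface", "parameter", "value"]
    )
    return controls, patient, patient_runs


# ---------------------------------------------------------------------------
# on-disk form: 8-bit TIFF + JSON truth sidecar
# ---------------------------------------------------------------------------


def _sidecar(path: Path, payload: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def save_scene(scene: SyntheticScene, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, scene.pixel_grid)
    _sidecar(
        path,
        {
            "truth_coverage": scene.truth_coverage,
            "truth_features": scene.truth_features,
            "pixel_size": scene.pixel_size,
            "seed": scene.seed,
        },
    )
    return path


def save_series(series: SyntheticSeries, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.stack(series.frames))
    stable_area = int(series.stable_mask.sum())
    _sidecar(
        path,
        {
            "frame_interval": series.frame_interval,
            "n_frames": len(series.frames),
            "stable_area_px": stable_area,
            "seed": series.seed,
        },
    )
    return path


def save_stack(stack: SyntheticStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.stack(stack.slices))
    _sidecar(
        path,
        {
            "slice_spacing": stack.slice_spacing,
            "truth_volume_per_area": stack.truth_volume_per_area,
            "pixel_size": stack.pixel_size,
            "seed": stack.seed,
        },
    )
    return path
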