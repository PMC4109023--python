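"""End-to-end pipeline: simulate → quantify → build matrix → cluster →
receptor model → patient profile, with a manifest for reproducibility.

One master seed in the config fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so each stage can be
re-run independently and the whole bundle is byte-identical under a fixed
seed. All numeric output is written with 10 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import cluster as cl
from . import imaging, panel, patients, receptors, synth

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "export_figures"]

log = logging.getLogger("thromboquant")

FLOAT_FMT = "%.10g"
_STAGES = (
    "simulate",
    "quantify",
    "build-matrix",
    "cluster",
    "receptor-model",
    "patient-profile",
)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; round-trips losslessly through YAML."""

    seed: int = 0
    shear: float = 1600.0  # wall shear rate, s⁻¹
    threshold: str | float = "otsu"  # 'otsu' or a fixed grey level
    # clustering
    n_boot: int = 200
    scales: list[float] = field(default_factory=lambda: list(cl.DEFAULT_SCALES))
    k: int = 3
    # PLS
    n_components: int = 3
    pls_scale: bool = False
    # statistics
    alpha: float = 0.05
    sd_multiplier: float = 2.0
    # synthetic study design
    n_surfaces: int = 52
    n_replicates: int = 3
    separation: float = 4.0
    matrix_noise_sd: float = 0.75
    receptor_noise_sd: float = 0.1
    cohort_surfaces: int = 9
    cohort_parameters: int = 6
    n_controls: int = 6
    n_days: int = 4
    inter_sd: float = 0.9
    intra_sd: float = 0.3
    patient_deficit_cells: int = 12
    patient_deficit_sd: float = -3.0
    n_demo_scenes: int = 3
    scene_size: int = 256

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if not (min(self.scales) < 1 < max(self.scales)):
            raise ValueError("bootstrap scales must straddle 1")
        if self.n_components < 1:
            raise ValueError("n_components must be ≥ 1")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError("threshold must be 'otsu' or a numeric grey level")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def threshold_policy(self):
        return "otsu" if self.threshold == "otsu" else ("fixed", float(self.threshold))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (below 2³¹)."""
    ss = np.random.SeedSequence(seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % 2**31)


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, float_format=FLOAT_FMT, **kw)
    return path


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages on simulated inputs and write a report bundle.

    Returns the manifest dict (also written as ``manifest.json``): config
    hash, seed, per-stage seeds and timings, and every artifact written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, i) for i, s in enumerate(_STAGES)},
        "artifacts": [],
    }
    files: list[Path] = []
    config.to_yaml(out / "config.yaml")
    files.append(out / "config.yaml")
    state: dict = {}
    for i, stage in enumerate(_STAGES):
        t0 = time.perf_counter()
        try:
            _RUNNERS[stage](config, stage_seed(config.seed, i), out, state, files)
        except Exception as err:  # noqa: BLE001 - halt with stage context
            raise StageError(stage, err) from err
        # timings go to the log only; the manifest must be seed-deterministic
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    manifest["artifacts"] = sorted(str(f.relative_to(out)) for f in files)
    _write_json(manifest, out / "manifest.json")
    return manifest


def _stage_simulate(cfg: PipelineConfig, seed: int, out: Path, state: dict, files: list) -> None:
    sim = out / "sim"
    sim.mkdir(exist_ok=True)
    size = (cfg.scene_size, cfg.scene_size)
    # feature scale tracks the field so the demo stays at ~10% coverage
    area = max(40.0, cfg.scene_size**2 / 400.0)
    for j in range(cfg.n_demo_scenes):
        scene = synth.gen_scene(25, seed=seed + j, shape=size, mean_area=area)
        files.append(synth.save_scene(scene, sim / f"scene_{j}.tif"))
        files.append((sim / f"scene_{j}.json"))
    series = synth.gen_series(
        synth.gen_scene(25, seed=seed + 100, shape=size, mean_area=area),
        0.5,
        seed=seed + 100,
    )
    files.append(synth.save_series(series, sim / "series.tif"))
    files.append(sim / "series.json")
    stack = synth.gen_stack(
        seed=seed + 200, shape=size, mean_area=400.0 * (cfg.scene_size / 256.0) ** 2
    )
    files.append(synth.save_stack(stack, sim / "stack.tif"))
    files.append(sim / "stack.json")
    state["series_truth"] = series
    state["stack_truth"] = stack

    mt = synth.planted_matrix_truth(
        seed=seed,
        n_surfaces=cfg.n_surfaces,
        separation=cfg.separation,
        noise_sd=cfg.matrix_noise_sd,
        n_replicates=cfg.n_replicates,
    )
    means, reps = synth.gen_parameter_matrix(mt)
    state["matrix_truth"], state["replicates"] = mt, reps
    files.append(_write_csv(reps, sim / "replicates.csv", index=False))

    rt = synth.planted_receptor_truth(seed=seed + 1, noise_sd=cfg.receptor_noise_sd)
    design = synth.gen_receptor_design(rt, cfg.n_surfaces)
    state["receptor_design"] = design
    files.append(_write_csv(design.assignment, sim / "assignment.csv"))

    rng = np.random.default_rng(seed + 2)
    ct = synth.cohort_truth(
        seed=seed + 2,
        n_surfaces=cfg.cohort_surfaces,
        parameters=synth.PARAMETERS[: cfg.cohort_parameters],
        n_controls=cfg.n_controls,
        n_days=cfg.n_days,
        inter_sd=cfg.inter_sd,
        intra_sd=cfg.intra_sd,
    )
    shift = ct.patient_shift.copy()
    cells = [(i, j) for i in range(shift.shape[0]) for j in range(shift.shape[1])]
    picks = rng.choice(len(cells), size=cfg.patient_deficit_cells, replace=False)
    for pick in picks:
        i, j = cells[pick]
        shift.iloc[i, j] = cfg.patient_deficit_sd
    ct.patient_shift = shift
    controls, patient, patient_runs = synth.gen_cohort(ct)
    state["cohort_truth"] = ct
    state["controls"], state["patient"], state["patient_runs"] = (
        controls,
        patient,
        patient_runs,
    )
    files.append(_write_csv(controls, sim / "controls.csv", index=False))
    files.append(_write_csv(patient, sim / "patient.csv", index=False))
    files.append(_write_csv(patient_runs, sim / "patient_runs.csv", index=False))
    files.append(_write_csv(shift, sim / "patient_shift_truth.csv"))


def _stage_quantify(cfg: PipelineConfig, seed: int, out: Path, state: dict, files: list) -> None:
    rows = []
    policy = cfg.threshold_policy
    for tif in sorted((out / "sim").glob("scene_*.tif")):
        img = tifffile.imread(tif)
        mask, cov = imaging.segment_coverage(img, policy)
        fs = imaging.feature_areas(mask)
        rows.append(
            {
                "image": tif.name,
                "parameter": "platelet_deposition",
                "value": cov,
            }
        )
        rows.append(
            {
                "image": tif.name,
                "parameter": "integrated_feature_size",
                "value": imaging.integrated_feature_size(fs),
            }
        )
        rows.append(
            {
                "image": tif.name,
                "parameter": "morphological_score",
                "value": imaging.morphological_score(mask, fs),
            }
        )
    series = tifffile.imread(out / "sim" / "series.tif")
    rows.append(
        {
            "image": "series.tif",
            "parameter": "stable_adhesion",
            "value": imaging.stable_adhesion(list(series)),
        }
    )
    stack_truth = state["stack_truth"]
    stack = tifffile.imread(out / "sim" / "stack.tif")
    rows.append(
        {
            "image": "stack.tif",
            "parameter": "thrombus_volume",
            "value": imaging.thrombus_volume(
                list(stack), stack_truth.slice_spacing, stack_truth.pixel_size, policy
            ),
        }
    )
    files.append(
        _write_csv(pd.DataFrame(rows), out / "image_parameters.csv", index=False)
    )


def _stage_matrix(cfg: PipelineConfig, seed: int, out: Path, state: dict, files: list) -> None:
    pm = panel.aggregate_replicates(state["replicates"], shear=cfg.shear)
    pm = panel.normalize_matrix(pm)
    state["pmatrix"] = pm
    files.append(_write_csv(pm.values, out / "matrix_raw.csv"))
    files.append(_write_csv(pm.normalized, out / "matrix_normalized.csv"))
    files.append(
        _write_json({k: list(v) for k, v in pm.bounds.items()}, out / "bounds.json")
    )
    cv = panel.compute_cv(state["controls"])
    files.append(_write_csv(cv.table, out / "variability.csv"))
    state["cv"] = cv


def _stage_cluster(cfg: PipelineConfig, seed: int, out: Path, state: dict, files: list) -> None:
    pm = state["pmatrix"]
    tree = cl.hcluster(pm.normalized)
    tree = cl.multiscale_bootstrap(
        pm.normalized, tree, scales=tuple(cfg.scales), n_boot=cfg.n_boot, seed=seed
    )
    assignment = cl.cut_types(tree, pm.normalized, k=cfg.k)
    state["tree"], state["types"] = tree, assignment
    (out / "tree.nwk").write_text(cl.newick_export(tree))
    files.append(out / "tree.nwk")
    files.append(_write_csv(tree.support, out / "cluster_support.csv"))
    files.append(_write_csv(assignment.types.to_frame(), out / "thrombus_types.csv"))
    det = panel.parameter_determination(pm.normalized, assignment.types)
    files.append(_write_csv(det, out / "parameter_determination.csv"))
    state["determination"] = det


def _stage_receptor(cfg: PipelineConfig, seed: int, out: Path, state: dict, files: list) -> None:
    design = state["receptor_design"]
    y = np.clip(np.floor(design.response + 0.5), 1, 3).astype(int)
    beta, rep, model = receptors.receptor_beta(
        design.assignment, y, cfg.n_components, shear=cfg.shear, scale=cfg.pls_scale
    )
    cv_rep, _ = receptors.crossval(
        design.assignment, y, cfg.n_components, scale=cfg.pls_scale
    )
    state["beta"], state["confusion"], state["cv_confusion"] = beta, rep, cv_rep
    files.append(_write_csv(beta.as_frame(), out / "beta_weights.csv"))
    files.append(
        _write_json(
            {
                "fit": {
                    "matrix": rep.matrix.to_numpy().tolist(),
                    "misassigned": rep.misassigned,
                },
                "cross_validation": {
                    "matrix": cv_rep.matrix.to_numpy().tolist(),
                    "misassigned": cv_rep.misassigned,
                },
                "n_surfaces": beta.n_surfaces,
                "x_variance_explained": list(beta.x_variance_explained),
            },
            out / "receptor_model.json",
        )
    )


def _stage_patient(cfg: PipelineConfig, seed: int, out: Path, state: dict, files: list) -> None:
    ref = patients.reference_ranges(state["controls"])
    smap = patients.significance_map(
        state["patient"], ref, sd_multiplier=cfg.sd_multiplier
    )
    diff, p, mask = patients.patient_subtraction(
        state["patient_runs"], state["controls"], alpha=cfg.alpha
    )
    summary = patients.deviation_summary(smap)
    state["ref"], state["smap"], state["summary"] = ref, smap, summary
    state["patient_diff"] = diff
    files.append(_write_csv(ref.mean, out / "reference_mean.csv"))
    files.append(_write_csv(ref.sd, out / "reference_sd.csv"))
    files.append(_write_csv(smap.flags, out / "significance_map.csv"))
    files.append(_write_csv(diff, out / "patient_subtraction.csv"))
    files.append(_write_csv(p, out / "patient_subtraction_p.csv"))
    files.append(_write_json(summary, out / "deviation_summary.json"))


_RUNNERS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "build-matrix": _stage_matrix,
    "cluster": _stage_cluster,
    "receptor-model": _stage_receptor,
    "patient-profile": _stage_patient,
}


def validate_inputs(paths: list[str | Path]) -> pd.DataFrame:
    """Schema-check CSV/TIFF inputs; report-only (one row per file)."""
    rows = []
    for p in map(Path, paths):
        status, message = "pass", ""
        try:
            if not p.exists():
                status, message = "fail", "file not found"
            elif p.suffix.lower() in (".tif", ".tiff"):
                img = tifffile.imread(p)
                if img.dtype not in (np.uint8, np.uint16):
                    status, message = (
                        "warn",
                        f"bit depth {img.dtype} will be auto-rescaled to 8-bit",
                    )
            elif p.suffix.lower() == ".csv":
                df = pd.read_csv(p)
                if df.empty:
                    status, message = "fail", "empty table"
                elif "assignment" in p.stem:
                    vals = df.select_dtypes("number").to_numpy()
                    bad = np.argwhere(~np.isin(vals, (0, 1)))
                    if bad.size:
                        r, c = bad[0]
                        status, message = (
                            "fail",
                            f"non-binary entry at row {r}, column "
                            f"{df.select_dtypes('number').columns[c]!r}",
                        )
            else:
                status, message = "warn", "unrecognized extension"
        except Exception as err:  # noqa: BLE001 - report, don't raise
            status, message = "fail", str(err)
        rows.append({"file": str(p), "status": status, "message": message})
    return pd.DataFrame(rows)


def export_figures(state_or_dir, outdir: str | Path) -> list[Path]:
    """Render the bundle's heatmap, dendrogram and significance map as PNGs.

    Accepts the directory of a finished run. Colour conventions: grey→black
    for normalized intensity, red (below) / green (above) for significance
    flags. Rendering order and colour scales are fixed, so re-exports are
    identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    src = Path(state_or_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    norm = pd.read_csv(src / "matrix_normalized.csv", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(norm.to_numpy(), cmap="Greys", vmin=0, vmax=10, aspect="auto")
    ax.set_xlabel("parameter")
    ax.set_ylabel("surface")
    ax.set_title("normalized thrombus parameters (0–10)")
    fig.savefig(outdir / "heatmap.png", dpi=100)
    plt.close(fig)
    written.append(outdir / "heatmap.png")

    tree_file = src / "tree.nwk"
    if tree_file.exists():
        from scipy.cluster.hierarchy import dendrogram

        support = pd.read_csv(src / "cluster_support.csv", index_col=0)
        n = len(norm)
        # rebuild a scipy-style linkage from the stored normalized matrix
        tree = cl.hcluster(norm)
        sizes = {i: 1 for i in range(n)}
        Z = []
        for i, (a, b, h) in enumerate(tree.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            Z.append([a, b, h, sizes[n + i]])
        fig, ax = plt.subplots(figsize=(10, 4))
        dendrogram(
            np.asarray(Z, dtype=float),
            labels=list(norm.index),
            ax=ax,
            color_threshold=0,
            link_color_func=lambda _k: "black",
        )
        ax.set_ylabel("complete-linkage height")
        fig.savefig(outdir / "dendrogram.png", dpi=100)
        plt.close(fig)
        written.append(outdir / "dendrogram.png")

    smap_file = src / "significance_map.csv"
    if smap_file.exists():
        flags = pd.read_csv(smap_file, index_col=0)
        fig, ax = plt.subplots(figsize=(6, 5))
        cmap = ListedColormap(["#c0392b", "#f5f5f5", "#27ae60"])
        ax.imshow(
            np.nan_to_num(flags.to_numpy()), cmap=cmap, vmin=-1, vmax=1, aspect="auto"
        )
        ax.set_xticks(range(len(flags.columns)))
        ax.set_xticklabels(flags.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(flags.index)))
        ax.set_yticklabels(flags.index, fontsize=7)
        ax.set_title("patient vs healthy mean ± 2 s.d.")
        fig.tight_layout()
        fig.savefig(outdir / "significance_map.png", dpi=100)
        plt.close(fig)
        written.append(outdir / "significance_map.png")
    return written
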