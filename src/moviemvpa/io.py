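"""Readers, writers and the end-to-end pipeline.

Voxel flattening order is fixed and documented: within a 3-D grid, x varies
fastest, then y, then z (Fortran order, 0-based indices).  Spatial maps are
un-flattened by the same order when exported.  Internal computation is
double precision; NIfTI export uses float32, the field's standard storage
type, so round trips are exact only to float32 resolution (~1e-7 relative).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierSpec, average_runs, fit_pca, project
from .dataset import RunMatrix, StudyDataset
from .evaluate import (
    SweepResult,
    lag_histogram,
    leave_one_run_out,
    pc_f_statistics,
    permutation_control,
    project_dataset_scores,
    sweep_froi,
)
from .features import anova_f_per_voxel, cut_froi
from .preprocess import preprocess_dataset
from .synth import GeneratorConfig, generate_dataset, voxel_grid_coords

logger = logging.getLogger("moviemvpa")


# ---------------------------------------------------------------- NIfTI I/O

def read_nifti_runs(
    paths: list[str | Path],
    label_paths: list[str | Path] | None = None,
    mask: str | Path | None = None,
    tr: float | None = None,
) -> StudyDataset:
    """Load one 4-D NIfTI file per run into a StudyDataset.

    Labels default to 0..T-1 (one class per volume); a label file, one
    integer per line, may override them per run.  A mask NIfTI restricts the
    voxel set; voxels are flattened x-fastest.
    """
    if label_paths is not None and len(label_paths) != len(paths):
        raise ValueError("need one label file per run (or none)")
    runs = []
    grid_shape = None
    mask_flat = None
    mask_name = "full-grid"
    if mask is not None:
        mask_img = nib.load(str(mask))
        mask_flat = np.asarray(mask_img.dataobj).ravel(order="F") > 0
        if mask_flat.sum() == 0:
            raise ValueError(f"mask {mask} selects 0 voxels")
        mask_name = Path(str(mask)).name
    n_t = None
    for i, path in enumerate(paths):
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=np.float64)
        if vol.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D volume, got shape {vol.shape}")
        if grid_shape is None:
            grid_shape = vol.shape[:3]
            if mask_flat is not None and mask_flat.size != np.prod(grid_shape):
                raise ValueError("mask grid does not match run grid")
        elif vol.shape[:3] != grid_shape:
            raise ValueError(f"{path}: grid {vol.shape[:3]} differs from {grid_shape}")
        t_this = vol.shape[3]
        if n_t is None:
            n_t = t_this
        elif t_this != n_t:
            raise ValueError(f"{path}: has {t_this} volumes, expected {n_t}")
        flat = vol.reshape(-1, t_this, order="F").T  # (T, V)
        if mask_flat is not None:
            flat = flat[:, mask_flat]
        if label_paths is not None:
            labels = np.loadtxt(str(label_paths[i]), dtype=int, ndmin=1)
            if labels.size != t_this:
                raise ValueError(
                    f"{label_paths[i]}: {labels.size} labels for {t_this} volumes in {path}"
                )
        else:
            labels = np.arange(t_this)
        run_tr = tr
        if run_tr is None:
            zooms = img.header.get_zooms()
            run_tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        runs.append(RunMatrix(data=flat, run_id=i, tr=run_tr, labels=labels))
    coords = voxel_grid_coords(grid_shape)
    if mask_flat is not None:
        coords = coords[mask_flat]
    return StudyDataset(
        runs=runs, voxel_coords=coords, mask_name=mask_name, grid_shape=tuple(grid_shape)
    )


def write_dataset_nifti(dataset: StudyDataset, out_dir: str | Path) -> list[Path]:
    """Export one float32 4-D NIfTI per run plus a label file per run."""
    if dataset.grid_shape is None:
        raise ValueError("dataset has no grid shape; cannot export volumes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for run in dataset.runs:
        vol = run.data.T.reshape(*dataset.grid_shape, run.n_timepoints, order="F")
        img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
        path = out_dir / f"run-{run.run_id:02d}.nii"
        nib.save(img, str(path))
        label_path = out_dir / f"run-{run.run_id:02d}_labels.txt"
        np.savetxt(str(label_path), run.labels, fmt="%d")
        written.extend([path, label_path])
    return written


def export_spatial_map(
    values: np.ndarray, dataset: StudyDataset, path: str | Path
) -> None:
    """Un-flatten a length-V spatial vector onto the grid and save as NIfTI."""
    if dataset.grid_shape is None:
        raise ValueError("dataset has no grid shape")
    full = np.zeros(int(np.prod(dataset.grid_shape)), dtype=np.float32)
    flat_idx = np.ravel_multi_index(dataset.voxel_coords.T, dataset.grid_shape, order="F")
    full[flat_idx] = values
    vol = full.reshape(dataset.grid_shape, order="F")
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


# ------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """Everything one end-to-end analysis needs, loadable from YAML/JSON."""

    data_source: dict
    specs: list[str] = field(default_factory=lambda: ["NNE", "NNC", "NME", "GNB64", "LDA64"])
    froi_sizes: list[int] | None = None
    n_pcs_grid: list[int] = field(default_factory=lambda: [8, 16, 32, 64, 128])
    n_permutations: int = 0
    n_export_pcs: int = 8
    seed: int = 0
    output_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        for name in self.specs:
            ClassifierSpec.from_name(name)  # validate before any computation
        kind = self.data_source.get("kind")
        if kind not in ("synthetic", "nifti"):
            raise ValueError("data_source.kind must be 'synthetic' or 'nifti'")
        if kind == "nifti":
            for key in ("paths",):
                for p in self.data_source.get(key, []):
                    if not Path(p).exists():
                        raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "data_source": self.data_source,
            "specs": list(self.specs),
            "froi_sizes": self.froi_sizes,
            "n_pcs_grid": list(self.n_pcs_grid),
            "n_permutations": self.n_permutations,
            "n_export_pcs": self.n_export_pcs,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_dataset(config: PipelineConfig) -> StudyDataset:
    src = config.data_source
    if src["kind"] == "synthetic":
        gen_cfg = GeneratorConfig.from_dict({**src.get("generator", {}), "seed": config.seed})
        dataset, _ = generate_dataset(gen_cfg)
        return dataset
    return read_nifti_runs(
        src["paths"],
        src.get("label_paths"),
        src.get("mask"),
        src.get("tr"),
    )


# ------------------------------------------------------------- orchestration

def _table_header(config: PipelineConfig) -> str:
    return f"# config_hash={config.hash()} seed={config.seed}\n"


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_table_header(config))
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Preprocess, cross-validate every spec over the fROI grid, and write
    the full set of report tables under ``config.output_dir``.

    Outputs: per-fold accuracy table, per-spec confusion matrix and lag
    histogram at that spec's best fROI size, per-PC F table, permutation
    null accuracies (if requested), back-projected PC maps as NIfTI, and a
    run log carrying the config hash, seed and fold timings.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={config.hash()}", f"seed={config.seed}"]

    dataset = load_dataset(config)
    dataset = preprocess_dataset(dataset)
    log_lines.append(
        f"dataset: R={dataset.n_runs} C={dataset.n_classes} V={dataset.n_voxels}"
    )

    sizes = config.froi_sizes
    if sizes is None:
        from .evaluate import default_froi_sizes

        sizes = default_froi_sizes(dataset.n_voxels)
    sizes = [int(min(s, dataset.n_voxels)) for s in sizes]

    acc_rows = []
    best: dict[str, tuple[int, object]] = {}
    for name in config.specs:
        spec = ClassifierSpec.from_name(name)
        t_spec = time.time()
        sweep = sweep_froi(dataset, spec, sizes)
        for size, cv in sorted(sweep.results.items()):
            for fold, acc in enumerate(cv.fold_accuracies):
                acc_rows.append(
                    {"spec": name, "froi_size": size, "fold": fold, "accuracy": acc,
                     "n_ties": cv.n_ties}
                )
        best_size = max(sweep.results, key=lambda s: sweep.results[s].mean_accuracy)
        best[name] = (best_size, sweep.results[best_size])
        log_lines.append(
            f"{name}: best froi={best_size} "
            f"mean_acc={sweep.results[best_size].mean_accuracy:.4f} "
            f"elapsed={time.time() - t_spec:.1f}s"
        )
    _write_table(pd.DataFrame(acc_rows), out / "accuracy_by_froi.csv", config)

    for name, (size, cv) in best.items():
        _write_table(
            pd.DataFrame(cv.confusion), out / f"confusion_{name}_froi{size}.csv", config
        )
        hist = lag_histogram(cv)
        _write_table(
            pd.DataFrame({"lag": hist.lags, "count": hist.counts}),
            out / f"lag_histogram_{name}_froi{size}.csv",
            config,
        )

    # per-PC F statistics in an all-run PCA basis over the largest fROI
    ranking = anova_f_per_voxel(dataset.runs)
    froi = cut_froi(ranking, max(sizes))
    n_pcs = min(max(config.n_pcs_grid), dataset.n_classes - 1, froi.size)
    scores, _ = project_dataset_scores(dataset, froi, n_pcs)
    f_pc = pc_f_statistics(scores)
    _write_table(
        pd.DataFrame({"pc": np.arange(1, n_pcs + 1), "f_stat": f_pc}),
        out / "pc_f_statistics.csv",
        config,
    )

    # back-projected spatial PC maps over the whole volume
    centroids_full = average_runs(dataset.runs)
    pca = fit_pca(centroids_full[:, froi], n_pcs)
    scores_c = project(centroids_full[:, froi], pca)
    centered = centroids_full - centroids_full.mean(axis=0)
    n_export = min(config.n_export_pcs, n_pcs)
    for k in range(n_export):
        s = scores_c[:, k]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (centered.T @ (s - s.mean())) / (
                np.linalg.norm(centered, axis=0) * np.linalg.norm(s - s.mean())
            )
        corr = np.nan_to_num(corr)
        export_spatial_map(corr, dataset, out / f"pc_map_{k + 1:02d}.nii")

    if config.n_permutations > 0:
        first = config.specs[0]
        size = best[first][0]
        null = permutation_control(
            dataset,
            ClassifierSpec.from_name(first),
            size,
            config.n_permutations,
            seed=config.seed + 1,
        )
        _write_table(
            pd.DataFrame({"permutation": np.arange(null.size), "mean_accuracy": null}),
            out / "permutation_null.csv",
            config,
        )
        log_lines.append(f"permutation null mean={null.mean():.5f} (spec={first})")

    log_lines.append(f"total_elapsed={time.time() - t0:.1f}s")
    log_lines.append(f"numpy={np.__version__} pandas={pd.__version__}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "output_dir": str(out),
        "best": {name: size for name, (size, _) in best.items()},
        "config_hash": config.hash(),
    }
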