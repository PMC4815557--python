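"""Per-run nuisance regression and voxel-wise z-scoring.

The decoding analysis assumes each run has been cleaned of slow scanner and
physiological drifts and brought to a common per-voxel scale: intercept,
linear and quadratic time trends (plus any user-supplied nuisance regressors,
e.g. motion parameters) are regressed out of every voxel time series, which
is then converted to a z-score over time.  Alignment and slice timing are
upstream concerns; this module ingests aligned data.
"""

from __future__ import annotations

import numpy as np

from .dataset import RunMatrix, StudyDataset

DEGENERATE_SD = 1e-12


def polynomial_regressors(n_timepoints: int) -> np.ndarray:
    """Design matrix [1, t, t^2] with t centered and scaled to [-1, 1]."""
    t = np.linspace(-1.0, 1.0, n_timepoints)
    return np.column_stack([np.ones(n_timepoints), t, t**2])


def regress_nuisance(run: RunMatrix, extra_regressors: np.ndarray | None = None) -> RunMatrix:
    """Replace each voxel column by its least-squares residual against
    [1, t, t^2, extras].

    Raises if the design matrix is rank-deficient (naming the collinear
    columns) or if there are too few time points to estimate it.
    """
    design = polynomial_regressors(run.n_timepoints)
    names = ["intercept", "linear", "quadratic"]
    if extra_regressors is not None and np.size(extra_regressors) > 0:
        extra = np.atleast_2d(np.asarray(extra_regressors, dtype=float))
        if extra.shape[0] != run.n_timepoints:
            raise ValueError(
                f"extra_regressors has {extra.shape[0]} rows, expected T={run.n_timepoints}"
            )
        design = np.column_stack([design, extra])
        names += [f"extra{i}" for i in range(extra.shape[1])]
    n_t, n_p = design.shape
    if n_t < n_p + 1:
        raise ValueError(f"T={n_t} too small to estimate {n_p} nuisance regressors")
    rank = np.linalg.matrix_rank(design)
    if rank < n_p:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    # Residual-maker via QR: r = y - Q Q^T y
    q, _ = np.linalg.qr(design)
    residual = run.data - q @ (q.T @ run.data)
    return run.with_data(residual)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(design.shape[1]):
        others = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
            bad.append(names[j])
    return bad


def zscore_voxels(run: RunMatrix) -> RunMatrix:
    """Standardize each voxel column over time (unbiased n-1 SD).

    Columns with SD below ``1e-12`` are set to all-zero instead of dividing
    by ~0; their indices are recorded in ``run.degenerate_voxels`` on the
    returned object.
    """
    if run.n_timepoints < 2:
        raise ValueError("z-scoring needs at least 2 time points")
    mean = run.data.mean(axis=0)
    sd = run.data.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd < DEGENERATE_SD)
    safe_sd = np.where(sd < DEGENERATE_SD, 1.0, sd)
    z = (run.data - mean) / safe_sd
    z[:, degenerate] = 0.0
    out = run.with_data(z)
    out.degenerate_voxels = degenerate
    return out


def preprocess_run(run: RunMatrix, extra_regressors: np.ndarray | None = None) -> RunMatrix:
    """Nuisance regression followed by z-scoring."""
    return zscore_voxels(regress_nuisance(run, extra_regressors))


def preprocess_dataset(
    dataset: StudyDataset,
    extra_regressors: list[np.ndarray | None] | None = None,
) -> StudyDataset:
    """Preprocess every run; ``extra_regressors`` is per-run or None."""
    if extra_regressors is None:
        extra_regressors = [None] * dataset.n_runs
    if len(extra_regressors) != dataset.n_runs:
        raise ValueError("need one extra_regressors entry (or None) per run")
    runs = [preprocess_run(r, x) for r, x in zip(dataset.runs, extra_regressors)]
    return StudyDataset(
        runs=runs,
        voxel_coords=dataset.voxel_coords,
        mask_name=dataset.mask_name,
        grid_shape=dataset.grid_shape,
        extra=dict(dataset.extra),
    )
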