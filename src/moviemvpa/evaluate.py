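"""Leave-one-run-out evaluation of volume decoding.

Cross-validation holds out one full run at a time; voxel ranking, templates,
PCA and covariance are all refitted on the remaining runs, so no data from
the held-out run ever informs the model.  On top of the per-fold accuracies
the module computes the analyses a decoding study reports: accuracy as a
function of fROI size and of PCA dimensionality, confusion matrices,
misclassification lag histograms, per-PC F statistics, and a permutation
control establishing the empirical chance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, fit, predict, average_runs, fit_pca, project
from .dataset import StudyDataset, RunMatrix
from .features import anova_f_per_voxel, anova_f_from_stack, cut_froi


@dataclass
class CvResult:
    """Aggregated leave-one-run-out outcome for one spec and fROI size."""

    spec: ClassifierSpec
    froi_size: int
    fold_accuracies: np.ndarray  # (R,) fraction correct per held-out run
    confusion: np.ndarray  # (C, C) integer counts, rows true, cols predicted
    n_ties: int
    nn_pairwise_accuracies: list[np.ndarray] | None = None  # per fold, (R-1,)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_from_confusion(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


@dataclass
class LagHistogram:
    """Counts of (predicted - true) class lags, in TR units."""

    lags: np.ndarray  # -(C-1) .. C-1
    counts: np.ndarray

    def fraction_at(self, lag: int) -> float:
        return float(self.counts[self.lags == lag][0] / self.counts.sum())


def leave_one_run_out(
    dataset: StudyDataset,
    spec: ClassifierSpec,
    froi_size: int,
    mask: np.ndarray | None = None,
    fold_hook=None,
) -> CvResult:
    """Cross-validate ``spec`` with a ``froi_size``-voxel training-data fROI.

    ``fold_hook(test_run_id, training_run_ids)``, if given, is called before
    each fold's feature selection — an instrumentation point for asserting
    that the held-out run never enters the training side.
    """
    if dataset.n_runs < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    n_classes = dataset.n_classes
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    fold_acc = np.empty(dataset.n_runs)
    n_ties = 0
    nn_pairwise = [] if spec.scheme == "nearest_neighbor" else None
    for i in range(dataset.n_runs):
        held, train = dataset.drop_run(i)
        if fold_hook is not None:
            fold_hook(held.run_id, [r.run_id for r in train])
        ranking = anova_f_per_voxel(train)
        froi = cut_froi(ranking, froi_size, mask)
        model = fit(train, spec, froi)
        result = predict(model, held)
        true = held.labels
        fold_acc[i] = np.mean(result.predicted == true)
        np.add.at(confusion, (true, result.predicted), 1)
        n_ties += result.n_ties
        if nn_pairwise is not None:
            nn_pairwise.append((result.per_run_predicted == true[None, :]).mean(axis=1))
    return CvResult(
        spec=spec,
        froi_size=froi_size,
        fold_accuracies=fold_acc,
        confusion=confusion,
        n_ties=n_ties,
        nn_pairwise_accuracies=nn_pairwise,
    )


@dataclass
class SweepResult:
    """CvResults keyed by the swept parameter, with a tidy summary table."""

    parameter: str
    results: dict[int, CvResult] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for value, cv in sorted(self.results.items()):
            acc = cv.fold_accuracies
            rows.append(
                {
                    self.parameter: value,
                    "spec": cv.spec.name,
                    "mean": acc.mean(),
                    "median": np.median(acc),
                    "q25": np.quantile(acc, 0.25),
                    "q75": np.quantile(acc, 0.75),
                    "min": acc.min(),
                    "max": acc.max(),
                    "n_ties": cv.n_ties,
                }
            )
        return pd.DataFrame(rows)


def default_froi_sizes(n_voxels: int) -> list[int]:
    """Powers of two from 16 up to 2^16, clipped to the available voxels."""
    sizes = [2**p for p in range(4, 17) if 2**p < n_voxels]
    sizes.append(n_voxels)
    return sizes


def sweep_froi(
    dataset: StudyDataset,
    spec: ClassifierSpec,
    sizes: list[int] | None = None,
    mask: np.ndarray | None = None,
) -> SweepResult:
    """Accuracy as a function of fROI size (the rise/peak/fall curve)."""
    if sizes is None:
        sizes = default_froi_sizes(dataset.n_voxels)
    out = SweepResult(parameter="froi_size")
    for k in sizes:
        out.results[int(k)] = leave_one_run_out(dataset, spec, int(k), mask)
    return out


def sweep_npcs(
    dataset: StudyDataset,
    spec: ClassifierSpec,
    froi_size: int,
    npcs_grid: list[int] = (8, 16, 32, 64, 128),
    mask: np.ndarray | None = None,
) -> SweepResult:
    """Accuracy as a function of PCA dimensionality at a fixed fROI size."""
    if spec.scheme != "nearest_mean":
        raise ValueError("the PC sweep applies to nearest-mean classifiers only")
    out = SweepResult(parameter="n_pcs")
    for k in npcs_grid:
        spec_k = ClassifierSpec(scheme=spec.scheme, metric=spec.metric, n_pcs=int(k))
        out.results[int(k)] = leave_one_run_out(dataset, spec_k, froi_size, mask)
    return out


def lag_histogram(cv: CvResult) -> LagHistogram:
    """Collapse the confusion matrix onto predicted-minus-true lags."""
    confusion = cv.confusion
    n_classes = confusion.shape[0]
    lags = np.arange(-(n_classes - 1), n_classes)
    counts = np.array([np.trace(confusion, offset=lag) for lag in lags])
    return LagHistogram(lags=lags, counts=counts)


def uniform_error_lag_fraction(confusion: np.ndarray, lag_abs: int = 1) -> float:
    """Expected fraction of *errors* at |lag| = lag_abs if each error fell
    uniformly on the C-1 wrong classes (the no-temporal-structure null)."""
    confusion = np.asarray(confusion)
    n_classes = confusion.shape[0]
    errors_per_class = confusion.sum(axis=1) - np.diag(confusion)
    total_errors = errors_per_class.sum()
    if total_errors == 0:
        return 0.0
    expected = 0.0
    for c in range(n_classes):
        n_at_lag = int(c - lag_abs >= 0) + int(c + lag_abs < n_classes)
        expected += errors_per_class[c] * n_at_lag / (n_classes - 1)
    return float(expected / total_errors)


def observed_error_lag_fraction(cv: CvResult, lag_abs: int = 1) -> float:
    """Fraction of misclassifications landing exactly lag_abs TRs away."""
    hist = lag_histogram(cv)
    errors = hist.counts.sum() - hist.counts[hist.lags == 0][0]
    if errors == 0:
        return 0.0
    at = hist.counts[np.abs(hist.lags) == lag_abs].sum()
    return float(at / errors)


def pc_f_statistics(projected_runs: list[np.ndarray]) -> np.ndarray:
    """Per-PC reproducibility F over runs (C groups, R replicates).

    ``projected_runs`` are (C, K) class-ordered score matrices of each run in
    a common PCA basis; the statistic is the same between/within variance
    ratio used for voxel ranking, applied to PC score time courses.
    """
    if len(projected_runs) < 2:
        raise ValueError("need >= 2 runs of PC scores")
    y = np.stack(projected_runs)  # (R, C, K)
    f, _, _ = anova_f_from_stack(y)
    return f


def project_dataset_scores(
    dataset: StudyDataset, froi: np.ndarray, n_pcs: int
) -> tuple[list[np.ndarray], "np.ndarray"]:
    """Fit PCA on the all-run average over ``froi`` and project every run.

    Convenience for the per-PC F analysis (not used inside cross-validation,
    where PCA is always refitted per fold).  Returns (per-run score
    matrices, centroid scores).
    """
    centroids = average_runs(dataset.runs)[:, froi]
    pca = fit_pca(centroids, n_pcs)
    scores = [project(r.by_class()[:, froi], pca) for r in dataset.runs]
    return scores, project(centroids, pca)


def permutation_control(
    dataset: StudyDataset,
    spec: ClassifierSpec,
    froi_size: int,
    n_perm: int,
    seed: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Empirical chance level: CV accuracy under within-run label permutation.

    Every run's labels are permuted independently (run structure preserved),
    with a fresh permutation per run per repetition from one seeded stream.
    Returns the per-permutation mean accuracies; their mean should sit at
    ~1/C for a sound pipeline.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null_acc = np.empty(n_perm)
    for p in range(n_perm):
        permuted_runs = [
            r.with_labels(rng.permutation(r.n_timepoints)) for r in dataset.runs
        ]
        permuted = StudyDataset(
            runs=permuted_runs,
            voxel_coords=dataset.voxel_coords,
            mask_name=dataset.mask_name,
            grid_shape=dataset.grid_shape,
        )
        null_acc[p] = leave_one_run_out(permuted, spec, froi_size, mask).mean_accuracy
    return null_acc
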