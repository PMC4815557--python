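"""Template-matching multi-class classifiers for volume decoding.

The family crosses two template schemes with four distance metrics:

========  =============  ======================  =====================
name      scheme         metric                  covariance
========  =============  ======================  =====================
NNC       nearest_neighbor  correlation          --
NNE       nearest_neighbor  euclidean            --
NMC[k]    nearest_mean   correlation             --
NME[k]    nearest_mean   euclidean               --
GNB[k]    nearest_mean   normalized_euclidean    diagonal within-class
LDA[k]    nearest_mean   mahalanobis             pooled within-class
========  =============  ======================  =====================

A trailing number k requests projection onto the top-k spatial principal
components of the run-averaged training templates before computing
distances.  The Mahalanobis metric requires this: the pooled within-class
covariance is rank-deficient in the raw voxel space whenever the number of
voxels exceeds the residual degrees of freedom, so LDA is only defined in a
reduced PC space.

All Euclidean-family distances are returned in *squared* form; the argmin
over class templates is invariant to the monotone square root, so one
convention serves every classifier.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .dataset import RunMatrix

SCHEMES = ("nearest_neighbor", "nearest_mean")
METRICS = ("correlation", "euclidean", "normalized_euclidean", "mahalanobis")

# Relative ridge added to covariance diagonals before inversion.
RIDGE_FRACTION = 1e-8


@dataclass(frozen=True)
class ClassifierSpec:
    """Template scheme x distance metric x optional PCA dimensionality.

    ``covariance_mode`` is implied by the metric (mahalanobis -> pooled,
    normalized_euclidean -> diagonal, otherwise none) and filled in
    automatically.
    """

    scheme: str
    metric: str
    n_pcs: int | None = None
    covariance_mode: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        implied = {"mahalanobis": "pooled", "normalized_euclidean": "diagonal"}.get(
            self.metric, "none"
        )
        if self.covariance_mode == "":
            object.__setattr__(self, "covariance_mode", implied)
        elif self.covariance_mode != implied:
            raise ValueError(
                f"metric {self.metric!r} implies covariance_mode {implied!r}, "
                f"got {self.covariance_mode!r}"
            )
        if self.metric == "mahalanobis" and self.n_pcs is None:
            raise ValueError(
                "mahalanobis requires n_pcs: the pooled covariance is rank-deficient "
                "and not invertible in the raw voxel space"
            )
        if self.scheme == "nearest_neighbor":
            if self.metric not in ("correlation", "euclidean"):
                raise ValueError("nearest_neighbor supports only correlation/euclidean")
            if self.n_pcs is not None:
                raise ValueError("nearest_neighbor templates are used in voxel space (no PCA)")

    @property
    def name(self) -> str:
        base = {
            ("nearest_neighbor", "correlation"): "NNC",
            ("nearest_neighbor", "euclidean"): "NNE",
            ("nearest_mean", "correlation"): "NMC",
            ("nearest_mean", "euclidean"): "NME",
            ("nearest_mean", "normalized_euclidean"): "GNB",
            ("nearest_mean", "mahalanobis"): "LDA",
        }[(self.scheme, self.metric)]
        return f"{base}{self.n_pcs}" if self.n_pcs is not None else base

    @classmethod
    def from_name(cls, name: str) -> "ClassifierSpec":
        """Parse names like ``NNC``, ``NME``, ``GNB64``, ``LDA32``."""
        m = re.fullmatch(r"(NNC|NNE|NMC|NME|GNB|LDA)(\d+)?", name.strip().upper())
        if not m:
            raise ValueError(f"unknown classifier name {name!r}")
        base, k = m.group(1), m.group(2)
        scheme = "nearest_neighbor" if base in ("NNC", "NNE") else "nearest_mean"
        metric = {
            "NNC": "correlation",
            "NNE": "euclidean",
            "NMC": "correlation",
            "NME": "euclidean",
            "GNB": "normalized_euclidean",
            "LDA": "mahalanobis",
        }[base]
        return cls(scheme=scheme, metric=metric, n_pcs=int(k) if k else None)


@dataclass
class PcaModel:
    """Spatial PCA basis fitted on run-averaged training templates.

    mean : (V,) column means of the template matrix.
    components : (V, K) orthonormal spatial eigenvectors, sign-fixed so each
        component's largest-magnitude loading is positive.
    eigenvalues : (K,) nonincreasing variances (squared singular values
        divided by C - 1).
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class ClassifierModel:
    spec: ClassifierSpec
    froi: np.ndarray
    centroids: np.ndarray | None = None  # (C, K or |froi|), nearest-mean only
    pooled_cov: np.ndarray | None = None  # (K, K) or (K,) diagonal
    pca: PcaModel | None = None
    training_templates: list[np.ndarray] | None = None  # NN: per-run (C, |froi|)
    training_template_run_ids: list[int] | None = None

    @property
    def n_classes(self) -> int:
        if self.centroids is not None:
            return self.centroids.shape[0]
        return self.training_templates[0].shape[0]


@dataclass
class PredictionResult:
    """Predictions for one test run, aligned with its data rows.

    ``distances`` is (T, C) for nearest-mean and (T, R_train, C) for
    nearest-neighbor (one distance block per template run).  For
    nearest-neighbor, ``per_run_predicted`` gives the (R_train, T) pairwise
    predictions obtained from each single template run, the unit the
    per-template-run accuracies are computed from.
    """

    predicted: np.ndarray
    distances: np.ndarray
    n_ties: int
    per_run_predicted: np.ndarray | None = None


def distance(y: np.ndarray, x_or_mu: np.ndarray, metric: str, cov=None) -> float:
    """Pairwise distance between two feature vectors (squared Euclid family).

    correlation: 1 - y.x / (|y||x|), in [0, 2]
    euclidean: |y - x|^2
    normalized_euclidean: sum_n (y_n - mu_n)^2 / Sigma_nn  (cov = diagonal)
    mahalanobis: (y - mu)^T Sigma^-1 (y - mu)              (cov = full SPD)
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_or_mu, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite input vector")
    needs_cov = metric in ("normalized_euclidean", "mahalanobis")
    if needs_cov and cov is None:
        raise ValueError(f"{metric} requires a covariance")
    if not needs_cov and cov is not None:
        raise ValueError(f"{metric} takes no covariance")
    return float(_distance_matrix(y[None, :], x[None, :], metric, cov)[0, 0])


def _distance_matrix(Y: np.ndarray, X: np.ndarray, metric: str, cov=None) -> np.ndarray:
    """(n, m) distances between rows of Y and rows of X."""
    if metric == "correlation":
        ny = np.linalg.norm(Y, axis=1)
        nx = np.linalg.norm(X, axis=1)
        if np.any(ny == 0) or np.any(nx == 0):
            raise ValueError("correlation distance undefined for zero-norm vectors")
        return 1.0 - (Y @ X.T) / np.outer(ny, nx)
    if metric == "euclidean":
        return cdist(Y, X, "sqeuclidean")
    if metric == "normalized_euclidean":
        d = np.asarray(cov, dtype=float)
        if d.ndim != 1 or np.any(d <= 0):
            raise ValueError("normalized_euclidean needs a positive diagonal covariance")
        w = 1.0 / np.sqrt(d)
        return cdist(Y * w, X * w, "sqeuclidean")
    if metric == "mahalanobis":
        sigma = np.asarray(cov, dtype=float)
        try:
            factor = cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError as e:
            raise ValueError("covariance is not positive-definite") from e
        # d(y, x) = (y-x)^T S^-1 (y-x); whiten rows with L^-1
        wy = cho_solve_half(factor, Y)
        wx = cho_solve_half(factor, X)
        return cdist(wy, wx, "sqeuclidean")
    raise ValueError(f"unknown metric {metric!r}")


def cho_solve_half(factor, A: np.ndarray) -> np.ndarray:
    """Rows of A multiplied by L^-1 (so squared Euclid = Mahalanobis)."""
    from scipy.linalg import solve_triangular

    L, lower = factor
    return solve_triangular(L, A.T, lower=lower).T


def average_runs(training_runs: list[RunMatrix]) -> np.ndarray:
    """(C, V) class centroids: mean over runs of the volume labelled c."""
    if not training_runs:
        raise ValueError("need at least one run")
    stacks = [r.by_class() for r in training_runs]
    shape = stacks[0].shape
    if any(s.shape != shape for s in stacks):
        raise ValueError("runs have inconsistent shapes")
    return np.mean(stacks, axis=0)


def fit_pca(centroids: np.ndarray, n_pcs: int) -> PcaModel:
    """Top-K spatial PCA of the column-centered (C, V) centroid matrix.

    Scores are *not* variance-normalized afterwards: components of large
    signal variance keep their scale, which is what the within-class
    covariance weighting of GNB/LDA then acts on.
    """
    centroids = np.asarray(centroids, dtype=float)
    n_classes, n_vox = centroids.shape
    max_k = min(n_classes - 1, n_vox)
    if not (1 <= n_pcs <= max_k):
        raise ValueError(f"n_pcs={n_pcs} outside [1, {max_k}] for a {centroids.shape} matrix")
    mean = centroids.mean(axis=0)
    centered = centroids - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds attainable rank {rank}")
    components = vt[:n_pcs].T  # (V, K)
    # deterministic sign: largest-|loading| entry positive
    flip = np.sign(components[np.abs(components).argmax(axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    components *= flip
    eigenvalues = s[:n_pcs] ** 2 / (n_classes - 1)
    return PcaModel(mean=mean, components=components, eigenvalues=eigenvalues)


def project(data: np.ndarray, pca: PcaModel) -> np.ndarray:
    """(T, K) scores: (data - mean) @ components, no score normalization."""
    data = np.asarray(data, dtype=float)
    if data.shape[1] != pca.mean.size:
        raise ValueError(
            f"data has {data.shape[1]} columns, PCA was fitted on {pca.mean.size}"
        )
    return (data - pca.mean) @ pca.components


def estimate_within_class_cov(
    projected_runs: list[np.ndarray],
    centroids_pc: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Pooled within-class covariance of training residuals.

    Residuals are score rows minus their class centroid, pooled over runs
    and classes; the maximum-likelihood divisor N (rather than N - C) is
    used since only relative weighting matters for the argmin.  A relative
    ridge ``1e-8 * trace / K`` keeps the result positive-definite.
    ``mode='diagonal'`` returns just the per-dimension variances.
    """
    if mode not in ("diagonal", "pooled"):
        raise ValueError(f"unknown covariance mode {mode!r}")
    if len(projected_runs) < 2:
        raise ValueError("covariance estimation needs >= 2 training runs")
    n_classes, k = centroids_pc.shape
    residuals = np.concatenate([scores - centroids_pc for scores in projected_runs])
    n_res = residuals.shape[0]
    if n_classes * (len(projected_runs) - 1) < k:
        warnings.warn(
            f"residual degrees of freedom {n_classes * (len(projected_runs) - 1)} < "
            f"dimension {k}; covariance estimate is poorly conditioned",
            stacklevel=2,
        )
    if not np.any(residuals):
        raise ValueError("all residuals are zero; within-class covariance is degenerate")
    if mode == "diagonal":
        var = (residuals**2).sum(axis=0) / n_res
        ridge = RIDGE_FRACTION * var.sum() / k
        return var + ridge
    sigma = residuals.T @ residuals / n_res
    ridge = RIDGE_FRACTION * np.trace(sigma) / k
    sigma = sigma + ridge * np.eye(k)
    return 0.5 * (sigma + sigma.T)


def fit(
    training_runs: list[RunMatrix],
    spec: ClassifierSpec,
    froi: np.ndarray,
) -> ClassifierModel:
    """Fit templates (and PCA/covariance where the spec asks) on training runs."""
    froi = np.asarray(froi, dtype=int)
    if froi.size == 0:
        raise ValueError("fROI must be nonempty")
    if spec.scheme == "nearest_neighbor":
        templates = [r.by_class()[:, froi] for r in training_runs]
        return ClassifierModel(
            spec=spec,
            froi=froi,
            training_templates=templates,
            training_template_run_ids=[r.run_id for r in training_runs],
        )

    centroids = average_runs(training_runs)[:, froi]
    pca = None
    if spec.n_pcs is not None:
        # A small fROI cannot support the requested dimensionality; clip to
        # the attainable maximum so fROI sweeps cover every size.
        k_eff = min(spec.n_pcs, centroids.shape[0] - 1, froi.size)
        pca = fit_pca(centroids, k_eff)
        centroids = project(centroids, pca)  # centroid scores
    cov = None
    if spec.covariance_mode != "none":
        stacks = [r.by_class()[:, froi] for r in training_runs]
        if pca is not None:
            stacks = [project(s, pca) for s in stacks]
        cov = estimate_within_class_cov(stacks, centroids, spec.covariance_mode)
    return ClassifierModel(spec=spec, froi=froi, centroids=centroids, pooled_cov=cov, pca=pca)


def predict(model: ClassifierModel, test_run: RunMatrix) -> PredictionResult:
    """Assign each test volume the class of its nearest template.

    Ties (equal minimal distances across classes) are broken by the lowest
    class index and counted in ``n_ties``.
    """
    spec = model.spec
    if test_run.n_voxels <= model.froi.max():
        raise ValueError(
            f"test run has {test_run.n_voxels} voxels, fROI indexes up to {model.froi.max()}"
        )
    x = test_run.data[:, model.froi]

    if spec.scheme == "nearest_neighbor":
        blocks = np.stack(
            [_distance_matrix(x, tmpl, spec.metric) for tmpl in model.training_templates]
        )  # (R_train, T, C)
        dist = np.transpose(blocks, (1, 0, 2))  # (T, R_train, C)
        flat_best = dist.reshape(dist.shape[0], -1).min(axis=1)
        per_class_min = dist.min(axis=1)  # (T, C)
        predicted = per_class_min.argmin(axis=1)
        n_ties = int(((per_class_min == flat_best[:, None]).sum(axis=1) > 1).sum())
        per_run_predicted = blocks.argmin(axis=2)  # (R_train, T)
        return PredictionResult(
            predicted=predicted,
            distances=dist,
            n_ties=n_ties,
            per_run_predicted=per_run_predicted,
        )

    if model.pca is not None:
        x = project(x, model.pca)
    dist = _distance_matrix(x, model.centroids, spec.metric, model.pooled_cov)
    predicted = dist.argmin(axis=1)
    best = dist.min(axis=1)
    n_ties = int(((dist == best[:, None]).sum(axis=1) > 1).sum())
    return PredictionResult(predicted=predicted, distances=dist, n_ties=n_ties)
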