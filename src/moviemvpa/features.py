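"""Voxel ranking by one-way ANOVA across stimulus time points.

Each of the C stimulus time points is treated as an independent group and
each run as a repeated measurement, giving a per-voxel F statistic
``MS_between / MS_within`` with C-1 and C*(R-1) degrees of freedom.  Cutting
the top-k voxels of the descending-F ordering yields a functional ROI (fROI)
of any requested size.  Within cross-validation the ranking must be computed
from training runs only; the evaluation layer enforces that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import RunMatrix


@dataclass
class FeatureRanking:
    """Per-voxel F statistics and the descending-F voxel ordering.

    ``order`` sorts F descending with ties (including +inf ties) broken by
    ascending voxel index.  Degenerate all-zero voxels get F = 0.
    """

    f_stat: np.ndarray
    order: np.ndarray
    df_between: int
    df_within: int

    @property
    def n_voxels(self) -> int:
        return self.f_stat.size

    def p_values(self) -> np.ndarray:
        """Upper-tail p-values under F(df_between, df_within); +inf maps to 0."""
        p = np.empty_like(self.f_stat)
        finite = np.isfinite(self.f_stat)
        p[finite] = stats.f.sf(self.f_stat[finite], self.df_between, self.df_within)
        p[~finite] = 0.0
        return p


def class_stacked(runs: list[RunMatrix]) -> np.ndarray:
    """Stack runs as an (R, C, V) array with axis 1 ordered by class label."""
    return np.stack([r.by_class() for r in runs])


def anova_f_from_stack(y: np.ndarray) -> tuple[np.ndarray, int, int]:
    """One-way ANOVA F for each column of an (R, C, M) replicate stack.

    Groups are the C classes, replicates the R runs.  Returns (F, df_between,
    df_within) with the conventions: ``MS_within = 0, MS_between > 0`` ->
    F = +inf (perfectly reproducible column); both zero -> F = 0 (flat).
    """
    y = np.asarray(y, dtype=float)
    n_runs, n_classes = y.shape[0], y.shape[1]
    if n_runs < 2:
        raise ValueError("ANOVA needs >= 2 runs to estimate within-group variance")
    group_mean = y.mean(axis=0)  # (C, M)
    grand_mean = group_mean.mean(axis=0)  # (M,)
    ss_between = n_runs * ((group_mean - grand_mean) ** 2).sum(axis=0)
    ss_within = ((y - group_mean) ** 2).sum(axis=(0, 1))
    df_between = n_classes - 1
    df_within = n_classes * (n_runs - 1)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    # ms_within of identical replicates may round to ~1e-32 instead of 0;
    # treat it as zero relative to ms_between
    zero_within = ms_within <= 1e-12 * ms_between
    f[(ms_within == 0) & (ms_between == 0)] = 0.0
    f[zero_within & (ms_between > 0)] = np.inf
    return f, df_between, df_within


def anova_f_per_voxel(training_runs: list[RunMatrix]) -> FeatureRanking:
    """Per-voxel stimulus-modulation F over C time-point groups, R_train runs."""
    f, df_between, df_within = anova_f_from_stack(class_stacked(training_runs))
    # stable sort on -F keeps ascending voxel index within ties (incl. +inf)
    order = np.argsort(-f, kind="stable")
    return FeatureRanking(f_stat=f, order=order, df_between=df_between, df_within=df_within)


def cut_froi(ranking: FeatureRanking, k: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k top-ranked voxels (optionally within a boolean mask)."""
    order = ranking.order
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ranking.n_voxels,):
            raise ValueError("mask must be a length-V boolean vector")
        order = order[mask[order]]
    if not (1 <= k <= order.size):
        raise ValueError(f"k={k} out of range [1, {order.size}]")
    return order[:k].copy()
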