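"""Core in-memory containers for multi-run voxel-by-time fMRI data.

A *run* is one complete presentation of the stimulus sequence: ``T`` volumes
acquired every ``tr`` seconds.  Each volume (time point) is its own stimulus
class, so the number of classes ``C`` equals ``T`` and the label vector of an
unpermuted run is simply ``0..T-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class RunMatrix:
    """One run's time-by-voxel data matrix.

    Parameters
    ----------
    data
        ``(T, V)`` float array, time points by voxels.
    run_id
        Identifier of the run (unique within a :class:`StudyDataset`).
    tr
        Repetition time in seconds (interval between volumes).
    labels
        Length-``T`` integer class labels.  Each class in ``0..C-1`` must
        occur exactly once per run (``C == T``); label permutation is how
        chance-level controls are constructed.
    """

    data: np.ndarray
    run_id: int
    tr: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (T, V) array")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match T={self.data.shape[0]}"
            )
        if not np.array_equal(np.sort(self.labels), np.arange(self.n_timepoints)):
            raise ValueError("labels must be a permutation of 0..T-1 (one volume per class)")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_classes(self) -> int:
        return self.n_timepoints

    def by_class(self) -> np.ndarray:
        """Return the ``(C, V)`` matrix with row ``c`` = the volume labelled ``c``."""
        order = np.argsort(self.labels, kind="stable")
        return self.data[order]

    def with_labels(self, labels: np.ndarray) -> "RunMatrix":
        return replace(self, labels=np.asarray(labels, dtype=int))

    def with_data(self, data: np.ndarray) -> "RunMatrix":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class StudyDataset:
    """Ordered collection of runs sharing one voxel index space.

    ``voxel_coords`` maps flat voxel index to 3-D grid indices (x fastest,
    then y, then z; 0-based), so spatial maps can be un-flattened for export.
    """

    runs: list[RunMatrix]
    voxel_coords: np.ndarray | None = None
    mask_name: str = "full-grid"
    grid_shape: tuple[int, int, int] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("dataset needs at least one run")
        v = self.runs[0].n_voxels
        t = self.runs[0].n_timepoints
        for r in self.runs:
            if r.n_voxels != v or r.n_timepoints != t:
                raise ValueError(
                    f"run {r.run_id}: shape {r.data.shape} inconsistent with (T={t}, V={v})"
                )
        if self.voxel_coords is not None:
            self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
            if self.voxel_coords.shape != (v, 3):
                raise ValueError("voxel_coords must have shape (V, 3)")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_voxels(self) -> int:
        return self.runs[0].n_voxels

    @property
    def n_classes(self) -> int:
        return self.runs[0].n_classes

    @property
    def tr(self) -> float:
        return self.runs[0].tr

    def drop_run(self, index: int) -> tuple[RunMatrix, list[RunMatrix]]:
        """Split into (held-out run, remaining runs) for cross-validation."""
        held = self.runs[index]
        rest = [r for i, r in enumerate(self.runs) if i != index]
        return held, rest
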