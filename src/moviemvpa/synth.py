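"""Synthetic multi-run BOLD fMRI generator.

Emulates the statistical structure a movie-decoding analysis relies on:
a small number of latent spatial signal components (smooth blobs over a voxel
grid) driven by stimulus-locked event trains convolved with a hemodynamic
response function (HRF), replayed identically in every run, then corrupted by
run-specific gain, additive offsets, low-order polynomial drift, and white
Gaussian noise.  A subpopulation of voxels carries no signal at all, so that
ANOVA-based voxel ranking has something meaningful to separate.

The defaults mirror a repeated-viewing movie paradigm: 8 runs of 150 volumes
at TR = 2 s (a 5-minute stimulus) on a 24 x 24 x 12 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dataset import RunMatrix, StudyDataset

# Dispersion (time constant, s) of each gamma lobe of the HRF.  0.9 s is the
# classical single-subject value; with a 6 s peak it yields a kernel of
# ~5-6 s FWHM, the width that makes consecutive volumes confusable.
HRF_DISPERSION = 0.9

# Probability per TR that a latent component's event train is "on".
EVENT_PROB = 0.3

# Duration (s) over which the HRF kernel is sampled and normalized.
HRF_SUPPORT = 32.0


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    ``snr`` is the signal-to-noise *amplitude* ratio: the temporal SD of the
    stimulus-locked signal, averaged over active voxels, divided by the white
    noise SD (fixed at 1).  ``snr = 0`` produces pure-noise data.
    """

    n_runs: int = 8
    n_timepoints: int = 150
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    n_components: int = 16
    frac_active_voxels: float = 0.25
    snr: float = 1.0
    hrf_peak: float = 6.0
    hrf_undershoot: float = 16.0
    hrf_ratio: float = 1.0 / 6.0
    drift_amp: float = 1.0
    run_gain_sd: float = 0.1
    run_offset_sd: float = 0.5
    amp_decay: float = 0.5
    n_noise_components: int = 0
    noise_component_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not (0.0 < self.frac_active_voxels <= 1.0):
            raise ValueError("frac_active_voxels must lie in (0, 1]")
        if self.n_components > self.n_timepoints:
            raise ValueError("n_components may not exceed n_timepoints")
        if self.frac_active_voxels * self.n_voxels < self.n_components:
            raise ValueError("too few active voxels to carry all signal components")
        if self.n_runs < 1 or self.n_timepoints < 2:
            raise ValueError("need n_runs >= 1 and n_timepoints >= 2")
        if self.n_noise_components < 0 or self.noise_component_scale < 0:
            raise ValueError("noise-component settings must be nonnegative")

    @property
    def n_voxels(self) -> int:
        x, y, z = self.grid_shape
        return x * y * z

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent structure behind a generated dataset.

    component_maps : (K, V) spatial loadings, zero outside the active mask.
    component_timecourses : (K, T) HRF-convolved, z-scored event signals,
        identical for every run before run-specific corruption.
    active_voxel_mask : (V,) bool, True where any signal is present.
    """

    component_maps: np.ndarray
    component_timecourses: np.ndarray
    active_voxel_mask: np.ndarray


def double_gamma_hrf(t, config: GeneratorConfig | None = None) -> np.ndarray:
    """Canonical two-gamma hemodynamic response, peak-normalized to 1.

    ``h(t) = g(t; peak) - ratio * g(t; undershoot)`` where
    ``g(t; p) = (t/p)**(p/d) * exp(-(t - p)/d)`` is a gamma-shaped lobe with
    its mode exactly at ``p`` (dispersion ``d`` fixed at 0.9 s).  The kernel
    is scaled so its maximum over a dense sampling of [0, 32] s equals 1.
    """
    if config is None:
        config = GeneratorConfig()
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")

    def raw(tt: np.ndarray) -> np.ndarray:
        return _gamma_lobe(tt, config.hrf_peak) - config.hrf_ratio * _gamma_lobe(
            tt, config.hrf_undershoot
        )

    dense = np.arange(0.0, HRF_SUPPORT + 1e-9, 0.01)
    peak_val = raw(dense).max()
    return raw(t) / peak_val


def _gamma_lobe(t: np.ndarray, peak: float, dispersion: float = HRF_DISPERSION) -> np.ndarray:
    a = peak / dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(t > 0, np.exp(a * np.log(np.maximum(t, 1e-300) / peak) - (t - peak) / dispersion), 0.0)
    return out


def _component_maps(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth sparse spatial loadings: 1-3 signed Gaussian blobs per component."""
    gx, gy, gz = config.grid_shape
    xs, ys, zs = np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij")
    maps = np.zeros((config.n_components, config.n_voxels))
    sigma_lo = max(1.0, min(config.grid_shape) / 8.0)
    sigma_hi = max(1.5, min(config.grid_shape) / 4.0)
    for k in range(config.n_components):
        n_blobs = int(rng.integers(1, 4))
        field = np.zeros(config.grid_shape)
        for _ in range(n_blobs):
            cx, cy, cz = rng.uniform(0, [gx, gy, gz])
            sx, sy, sz = rng.uniform(sigma_lo, sigma_hi, size=3)
            sign = rng.choice([-1.0, 1.0])
            field += sign * np.exp(
                -0.5 * (((xs - cx) / sx) ** 2 + ((ys - cy) / sy) ** 2 + ((zs - cz) / sz) ** 2)
            )
        # x fastest, then y, then z
        maps[k] = field.ravel(order="F")
    return maps


def _event_timecourses(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Binary event trains convolved with the HRF, z-scored and decorrelated.

    Independent Bernoulli event trains convolved with a ~5 s kernel end up
    substantially cross-correlated over only 150 samples, which would make
    the latent components unidentifiable for PCA even without noise.  A ZCA
    (symmetric) whitening step therefore renders the component timecourses
    exactly uncorrelated over the run while staying as close as possible to
    the original HRF-smooth trains; smoothness and the resulting
    adjacent-time-point confusability are preserved.
    """
    events = (rng.random((config.n_components, config.n_timepoints)) < EVENT_PROB).astype(float)
    kernel_t = np.arange(0.0, HRF_SUPPORT + 1e-9, config.tr)
    kernel = double_gamma_hrf(kernel_t, config)
    tcs = np.empty_like(events)
    for k in range(config.n_components):
        conv = np.convolve(events[k], kernel)[: config.n_timepoints]
        sd = conv.std()
        if sd < 1e-12:  # pathological all-off/all-on train; keep deterministic
            tcs[k] = 0.0
        else:
            tcs[k] = (conv - conv.mean()) / sd
    if config.n_components > 1:
        gram = tcs @ tcs.T / config.n_timepoints
        eigval, eigvec = np.linalg.eigh(gram)
        keep = eigval > 1e-10 * eigval.max()
        inv_sqrt = (eigvec[:, keep] / np.sqrt(eigval[keep])) @ eigvec[:, keep].T
        tcs = inv_sqrt @ tcs
    return tcs


def voxel_grid_coords(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """(V, 3) grid indices for the fixed flattening order (x fastest, y, z)."""
    gx, gy, gz = grid_shape
    idx = np.arange(gx * gy * gz)
    return np.stack([idx % gx, (idx // gx) % gy, idx // (gx * gy)], axis=1)


def _noise_component_maps(config: GeneratorConfig, rng: np.random.Generator, signal_peak: float) -> np.ndarray:
    """Spatial maps of structured noise sources (vascular/arousal-like).

    Smooth blobs anywhere in the volume, peak-normalized per map and scaled
    relative to the strongest signal loading, so ``noise_component_scale``
    is a dimensionless amplitude ratio.  These are high-variance,
    stimulus-unrelated directions in pattern space — the kind of noise a
    within-class covariance estimate can learn to suppress.
    """
    n = config.n_noise_components
    blob_cfg = GeneratorConfig(
        grid_shape=config.grid_shape,
        n_components=max(n, 1),
        n_timepoints=config.n_timepoints,
        seed=config.seed,
    )
    nmaps = _component_maps(blob_cfg, rng)[:n]
    peak = np.abs(nmaps).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return nmaps / peak * (config.noise_component_scale * signal_peak)


def generate_dataset(config: GeneratorConfig) -> tuple[StudyDataset, GroundTruth]:
    """Generate raw (un-preprocessed) multi-run data plus its ground truth.

    Each run equals ``gain_r * signal + offset_r + drift_r(t) + structured
    noise + white noise`` with the stimulus-locked signal
    ``sum_k map_k (x) timecourse_k`` shared across runs.  Component maps get
    disjoint spatial supports (each active voxel belongs to the component
    loading it most strongly) and a ``k**-amp_decay`` amplitude spectrum, so
    latent components are orthogonal with distinct variances — the structure
    spatial PCA can recover.  Structured noise (if configured) is white in
    time but spatially low-rank, independent of the signal components.

    Randomness is drawn from a single seeded stream in a fixed order:
    component maps, event trains, noise-component maps, then per run (gain,
    offsets, drift coefficients, noise-component timecourses, white noise),
    so the same seed reproduces the data bit-for-bit and changing ``snr``
    alone changes only the signal amplitude.
    """
    rng = np.random.default_rng(config.seed)
    maps = _component_maps(config, rng)
    tcs = _event_timecourses(config, rng)

    # Active mask = the frac_active_voxels share of voxels with the strongest
    # loading on any component; maps are zeroed outside it.
    strength = np.abs(maps).max(axis=0)
    n_active = max(config.n_components, int(round(config.frac_active_voxels * config.n_voxels)))
    active = np.zeros(config.n_voxels, dtype=bool)
    active[np.argsort(-strength, kind="stable")[:n_active]] = True

    # Winner-take-all supports: a voxel loads only on its strongest
    # component, giving orthogonal maps (distinct functional regions).
    winner = np.abs(maps).argmax(axis=0)
    wta = np.zeros_like(maps)
    cols = np.arange(config.n_voxels)
    wta[winner, cols] = maps[winner, cols]
    wta[:, ~active] = 0.0
    maps = wta * (np.arange(1, config.n_components + 1) ** -config.amp_decay)[:, None]

    # Global scale so the mean temporal SD of the signal over active voxels
    # equals snr (white noise SD is 1).
    signal = tcs.T @ maps  # (T, V)
    sd_active = signal[:, active].std(axis=0)
    mean_sd = sd_active.mean()
    scale = config.snr / mean_sd if (config.snr > 0 and mean_sd > 1e-12) else 0.0
    maps *= scale
    signal *= scale

    nmaps = None
    if config.n_noise_components > 0 and config.noise_component_scale > 0:
        nmaps = _noise_component_maps(config, rng, np.abs(maps).max())

    t_norm = np.linspace(-1.0, 1.0, config.n_timepoints)
    labels = np.arange(config.n_timepoints)
    runs = []
    for r in range(config.n_runs):
        gain = 1.0 + config.run_gain_sd * rng.standard_normal()
        offset = config.run_offset_sd * rng.standard_normal(config.n_voxels)
        a_r, b_r = config.drift_amp * rng.standard_normal(2)
        drift = a_r * t_norm + b_r * t_norm**2
        data = gain * signal + offset[None, :] + drift[:, None]
        if nmaps is not None:
            data = data + rng.standard_normal(
                (config.n_timepoints, config.n_noise_components)
            ) @ nmaps
        data = data + rng.standard_normal((config.n_timepoints, config.n_voxels))
        runs.append(RunMatrix(data=data, run_id=r, tr=config.tr, labels=labels.copy()))

    dataset = StudyDataset(
        runs=runs,
        voxel_coords=voxel_grid_coords(config.grid_shape),
        mask_name="synthetic-grid",
        grid_shape=config.grid_shape,
        extra={"config": config.to_dict()},
    )
    truth = GroundTruth(
        component_maps=maps,
        component_timecourses=tcs,
        active_voxel_mask=active,
    )
    return dataset, truth


def fixture_config(seed: int = 0) -> GeneratorConfig:
    """Moderate-SNR study conditions used for the classifier comparison.

    A reduced grid keeps the full cross-validated fROI sweep tractable while
    preserving the regime of interest: many confusable classes (C = 150),
    few runs, a minority of informative voxels, a signal of high latent
    dimensionality (64 components, so a 64-dimensional PC space is not
    padded with noise directions), and structured noise components strong
    enough that template averaging and covariance weighting visibly matter.
    """
    return GeneratorConfig(
        n_runs=8,
        n_timepoints=150,
        grid_shape=(16, 16, 12),
        n_components=64,
        frac_active_voxels=0.25,
        snr=0.5,
        drift_amp=1.0,
        run_gain_sd=0.1,
        run_offset_sd=0.5,
        amp_decay=0.5,
        n_noise_components=8,
        noise_component_scale=0.8,
        seed=seed,
    )
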