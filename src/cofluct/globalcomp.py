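"""Global fMRI signal extraction via PCA and complex PCA.

The first principal component of the frames x voxels matrix captures the
zero-lag global fluctuation; the first *complex* principal component of
the Hilbert-transformed data additionally encodes per-voxel time delays
in its phase angles (traveling-wave structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .filters import bandpass, check_band_duration

TISSUES = ("gray", "white", "csf", "vein", "other")


@dataclass
class VoxelTimeSeries:
    """Frames x voxels matrix with geometry and optional tissue labels."""

    data: np.ndarray
    tr_s: float
    mask_coords: np.ndarray | None = None  # voxels x 3 integer lattice coords
    voxel_size_mm: float = 3.0
    tissue_label: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be frames x voxels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class RealComponent:
    weights: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: float
    sign_convention: str = "gray_mean_positive"


@dataclass
class ComplexComponent:
    weights: np.ndarray  # complex, unit norm
    scores: np.ndarray  # complex
    phase_delay_map: np.ndarray  # radians in [0, 2pi)
    explained_variance_ratio: float
    phase_convention: str = "gray_mean_real_positive"


def _smooth_spatial(vts: VoxelTimeSeries, fwhm_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing on the voxel lattice (mask-normalized)."""
    coords = vts.mask_coords
    if coords is None:
        raise ValueError("spatial smoothing requires mask coordinates")
    coords = np.asarray(coords, dtype=int)
    dims = coords.max(axis=0) + 1
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vts.voxel_size_mm
    mask = np.zeros(dims, dtype=float)
    mask[tuple(coords.T)] = 1.0
    smooth_mask = ndimage.gaussian_filter(mask, sigma)
    out = np.empty_like(vts.data)
    vol = np.zeros(dims, dtype=float)
    for t in range(vts.n_frames):
        vol[:] = 0.0
        vol[tuple(coords.T)] = vts.data[t]
        sm = ndimage.gaussian_filter(vol, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = sm / smooth_mask
        out[t] = sm[tuple(coords.T)]
    return out


def preprocess_bold(raw: VoxelTimeSeries, smoothing_fwhm_mm: float = 5.0,
                    band=(0.01, 0.1), order: int = 5) -> VoxelTimeSeries:
    """Spatial smoothing (default FWHM 5 mm), zero-phase fifth-order
    0.01-0.1 Hz bandpass along time, then per-voxel demeaning."""
    fs = 1.0 / raw.tr_s
    check_band_duration(raw.n_frames, fs, band[0])
    data = raw.data
    if smoothing_fwhm_mm > 0:
        data = _smooth_spatial(raw, smoothing_fwhm_mm)
    data = bandpass(data, fs, band=band, order=order, axis=0)
    data = data - data.mean(axis=0, keepdims=True)
    return VoxelTimeSeries(data=data, tr_s=raw.tr_s, mask_coords=raw.mask_coords,
                           voxel_size_mm=raw.voxel_size_mm,
                           tissue_label=raw.tissue_label, subject_id=raw.subject_id)


def _concatenate(runs, zscore_runs: bool) -> tuple[np.ndarray, VoxelTimeSeries]:
    if isinstance(runs, VoxelTimeSeries):
        runs = [runs]
    if not runs:
        raise ValueError("no runs supplied")
    n_vox = runs[0].n_voxels
    for r in runs[1:]:
        if r.n_voxels != n_vox:
            raise ValueError("voxel mask mismatch across runs")
    mats = []
    for r in runs:
        x = r.data - r.data.mean(axis=0, keepdims=True)
        if zscore_runs:
            sd = x.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            x = x / sd
        mats.append(x)
    return np.vstack(mats), runs[0]


def _randomized_svd(x: np.ndarray, rank: int = 1, n_oversample: int = 10,
                    n_iter: int = 7, seed: int = 0):
    """Randomized range-finder SVD; supports real and complex matrices."""
    rng = np.random.default_rng(seed)
    n = x.shape[1]
    k = min(rank + n_oversample, min(x.shape))
    omega = rng.standard_normal((n, k))
    if np.iscomplexobj(x):
        omega = omega + 1j * rng.standard_normal((n, k))
    y = x @ omega
    for _ in range(n_iter):
        y = x @ (x.conj().T @ y)
        y, _ = np.linalg.qr(y)
    q, _ = np.linalg.qr(y)
    b = q.conj().T @ x
    ub, s, vh = np.linalg.svd(b, full_matrices=False)
    u = q @ ub
    return u[:, :rank], s[:rank], vh[:rank]


def _first_component(x: np.ndarray, solver: str, seed: int = 0):
    if solver == "exact":
        u, s, vh = np.linalg.svd(x, full_matrices=False)
        u, s, vh = u[:, :1], s[:1], vh[:1]
    elif solver == "randomized":
        u, s, vh = _randomized_svd(x, rank=1, seed=seed)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    total_var = np.sum(np.abs(x) ** 2)
    evr = float(s[0] ** 2 / total_var)
    weights = vh[0].conj()  # voxel loadings v with x ~ scores @ v^H
    scores = x @ weights
    return weights, scores, evr


def _tissue_mean(weights: np.ndarray, labels: np.ndarray | None):
    if labels is not None and np.any(labels == "gray"):
        return weights[labels == "gray"].mean()
    return weights.mean()


def fit_pca(runs, solver: str = "exact", zscore_runs: bool = True,
            seed: int = 0) -> RealComponent:
    """First principal component of temporally concatenated runs.

    The component sign is flipped so the mean weight over gray-labeled
    voxels (all voxels, if no labels) is positive.
    """
    x, ref = _concatenate(runs, zscore_runs)
    weights, scores, evr = _first_component(x, solver, seed)
    if _tissue_mean(weights, ref.tissue_label) < 0:
        weights = -weights
        scores = -scores
    return RealComponent(weights=weights.real, scores=scores.real,
                         explained_variance_ratio=evr)


def fit_cpca(runs, solver: str = "exact", zscore_runs: bool = True,
             seed: int = 0, phase_reference: np.ndarray | None = None
             ) -> ComplexComponent:
    """First complex principal component of Hilbert-transformed runs.

    ``phase_delay_map`` is the angle of the voxel loadings mapped to
    [0, 2pi): larger angle = later arrival of the traveling wave. The
    global phase is fixed by rotating the component so the gray-voxel
    mean weight is real and positive; alternatively, pass a real-valued
    ``phase_reference`` series (e.g. inverted PPG amplitude) and the
    component is rotated so the scores are in phase with its analytic
    signal at lag zero.
    """
    if isinstance(runs, VoxelTimeSeries):
        runs = [runs]
    if not runs:
        raise ValueError("no runs supplied")
    n_vox = runs[0].n_voxels
    mats = []
    for r in runs:
        if r.n_voxels != n_vox:
            raise ValueError("voxel mask mismatch across runs")
        x = r.data - r.data.mean(axis=0, keepdims=True)
        z = signal.hilbert(x, axis=0)
        if zscore_runs:
            sd = x.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            z = z / sd
        mats.append(z)
    x = np.vstack(mats)
    weights, scores, evr = _first_component(x, solver, seed)
    if phase_reference is not None:
        ref = signal.hilbert(np.asarray(phase_reference, dtype=float)
                             - np.mean(phase_reference))
        if ref.size != scores.size:
            raise ValueError("phase_reference length must match total frames")
        rot = np.vdot(ref, scores)
        convention = "reference_locked"
    else:
        rot = _tissue_mean(weights, runs[0].tissue_label)
        convention = "gray_mean_real_positive"
    theta = np.angle(rot) if rot != 0 else 0.0
    weights = weights * np.exp(-1j * theta)
    scores = scores * np.exp(-1j * theta)
    phase = np.mod(np.angle(weights), 2 * np.pi)
    return ComplexComponent(weights=weights, scores=scores,
                            phase_delay_map=phase,
                            explained_variance_ratio=evr,
                            phase_convention=convention)


def reconstruct_movie(comp: ComplexComponent, n_bins: int = 30) -> np.ndarray:
    """Phase-binned temporal reconstruction of a complex component.

    Frames are assigned to ``n_bins`` equal phase bins by the angle of
    the component scores; the real-valued voxel-space projection
    Re(scores x weights^H) is averaged within each bin. Returns an
    n_bins x voxels array ordered by bin center phase.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    phases = np.mod(np.angle(comp.scores), 2 * np.pi)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    which = np.clip(np.digitize(phases, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    if np.any(counts == 0):
        occupancy = ", ".join(f"bin{k}={c}" for k, c in enumerate(counts))
        raise ValueError(f"empty phase bin(s); occupancy: {occupancy}")
    proj = np.real(comp.scores[:, None] * comp.weights[None, :].conj())
    maps = np.empty((n_bins, comp.weights.size))
    for k in range(n_bins):
        maps[k] = proj[which == k].mean(axis=0)
    return maps


def bin_centers(n_bins: int = 30) -> np.ndarray:
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    return (edges[:-1] + edges[1:]) / 2
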