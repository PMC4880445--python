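"""Map simulation and the cryo-EM map-validation stack.

Implements the standard half-map validation procedure: tight masking with a
soft edge, Fourier shell correlation (FSC), phase randomization beyond a
resolution limit, correction of the masked FSC for mask-induced correlation
(FSC_true = (FSC_t - FSC_n) / (1 - FSC_n) beyond the randomization limit),
threshold crossing at 0.143 (half maps) or 0.5 (map vs model), B-factor
sharpening exp(-B s^2 / 4), and a model-to-map Fourier agreement score.

Maps are plain 3D float grids with a cubic voxel size (default 2.8 A) and an
origin; all Fourier operations preserve Hermitian symmetry so maps stay real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityMap",
    "FSCCurve",
    "simulate_map",
    "sharpen",
    "tight_mask",
    "phase_randomize",
    "fsc",
    "fsc_true",
    "resolution_at_threshold",
    "model_map_agreement",
]

DEFAULT_VOXEL = 2.8  # A, final reconstruction pixel size


@dataclass
class DensityMap:
    """A 3D scalar grid. `data` is indexed [ix, iy, iz]; `origin` is the
    world-space position of voxel (0, 0, 0); cubic voxels of `voxel` A."""

    data: np.ndarray
    voxel: float = DEFAULT_VOXEL
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        if self.data.ndim != 3:
            raise ValueError("density grid must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def require_fourier_ready(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("grid dimensions must be >= 8 per axis for Fourier ops")

    def like(self, data: np.ndarray) -> "DensityMap":
        return DensityMap(data, self.voxel, self.origin.copy())

    def copy(self) -> "DensityMap":
        return self.like(self.data.copy())


@dataclass
class FSCCurve:
    """Per-shell correlation values at shell-center spatial frequencies."""

    freqs: np.ndarray   # 1/A, strictly increasing shell centers
    values: np.ndarray  # correlation per shell, |v| <= 1
    counts: np.ndarray  # Fourier voxels per shell

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-9:
            raise ValueError("FSC values must lie in [-1, 1]")


def _freq_grid(shape, voxel) -> np.ndarray:
    fx = np.fft.fftfreq(shape[0], d=voxel)
    fy = np.fft.fftfreq(shape[1], d=voxel)
    fz = np.fft.fftfreq(shape[2], d=voxel)
    return np.sqrt(
        fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    )


def _shell_index(shape, voxel, min_count: int = 10):
    """Assign each Fourier voxel to a one-voxel-wide shell; shells with fewer
    than `min_count` voxels are merged into their inner neighbor."""
    s = _freq_grid(shape, voxel)
    dstep = 1.0 / (max(shape) * voxel)
    idx = np.floor(s / dstep + 0.5).astype(int)
    nyq = 1.0 / (2.0 * voxel)
    idx[s > nyq] = -1  # outside the Nyquist sphere
    nshell = idx.max() + 1
    counts = np.bincount(idx[idx >= 0].ravel(), minlength=nshell)
    remap = np.arange(nshell)
    for k in range(1, nshell):
        if counts[remap[k]] < min_count and k > 0:
            remap[k] = remap[k - 1]
    idx = np.where(idx >= 0, remap[np.clip(idx, 0, None)], -1)
    return idx, dstep


def simulate_map(
    model,
    voxel: float = DEFAULT_VOXEL,
    resolution: float = 11.0,
    shape: tuple[int, int, int] | None = None,
    origin: np.ndarray | None = None,
    pad: float = 20.0,
) -> DensityMap:
    """Forward-simulate a density map from a pseudo-atom model.

    Each pseudo-atom contributes an isotropic Gaussian with sigma =
    resolution / (pi * sqrt(2)) weighted by radius^3 (mass ~ volume); DNA bp
    origins contribute with an effective 4 A radius.  `model` may be an
    AssemblyModel or an (n, 3) array (unit radii).
    """
    positions, radii = _model_points(model)
    if len(positions) == 0:
        raise ValueError("model contributes no pseudo-atoms")
    if resolution < 2.0 * voxel:
        raise ValueError(
            f"resolution {resolution} A violates Nyquist for voxel {voxel} A"
        )
    sigma = resolution / (np.pi * np.sqrt(2.0))
    if origin is None:
        origin = positions.min(axis=0) - pad
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        extent = positions.max(axis=0) + pad - origin
        shape = tuple(int(np.ceil(e / voxel)) + 1 for e in extent)
    grid = np.zeros(shape, dtype=np.float64)
    half = int(np.ceil(4.0 * sigma / voxel))
    axes = [np.arange(n) for n in shape]
    w = radii**3
    for p, wi in zip(positions, w):
        ci = (p - origin) / voxel
        lo = np.maximum(np.floor(ci).astype(int) - half, 0)
        hi = np.minimum(np.floor(ci).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        dx = (axes[0][lo[0]:hi[0]] - ci[0]) * voxel
        dy = (axes[1][lo[1]:hi[1]] - ci[1]) * voxel
        dz = (axes[2][lo[2]:hi[2]] - ci[2]) * voxel
        g = (
            np.exp(-(dx**2) / (2 * sigma**2))[:, None, None]
            * np.exp(-(dy**2) / (2 * sigma**2))[None, :, None]
            * np.exp(-(dz**2) / (2 * sigma**2))[None, None, :]
        )
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += wi * g
    return DensityMap(grid, voxel, origin)


def _model_points(model) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(model, "all_pseudo_atoms"):
        pos, rad = model.all_pseudo_atoms()
        dna_pos = [p.origins for p in model.dna.values()]
        dna_pos.append(model.junction.overlap_bp_origins())
        dpos = np.concatenate(dna_pos)
        pos = np.concatenate([pos, dpos]) if len(pos) else dpos
        rad = np.concatenate([rad, np.full(len(dpos), 4.0)])
        return pos, rad
    pos = np.atleast_2d(np.asarray(model, dtype=float))
    return pos, np.ones(len(pos))


def sharpen(density: DensityMap, bfactor: float) -> DensityMap:
    """Scale Fourier amplitudes by exp(-B s^2 / 4); phases untouched.

    Negative B sharpens (the final reconstruction used B = -2500 A^2 after
    filtering at the map resolution)."""
    density.require_fourier_ready()
    f = np.fft.fftn(density.data.astype(np.float64))
    s = _freq_grid(density.shape, density.voxel)
    f *= np.exp(-bfactor * s**2 / 4.0)
    return density.like(np.real(np.fft.ifftn(f)))


def tight_mask(
    density: DensityMap,
    threshold: float,
    margin: float = 15.0,
    soft_edge_voxels: float = 5.0,
) -> DensityMap:
    """Binary support above `threshold`, dilated by `margin` (A), with a
    raised-cosine soft edge of `soft_edge_voxels` voxels."""
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    support = density.data > threshold
    if not support.any():
        raise ValueError("threshold excludes the entire map; no support to mask")
    dist = ndimage.distance_transform_edt(~support) * density.voxel
    mask = np.zeros(density.shape, dtype=np.float64)
    inside = dist <= margin
    mask[inside] = 1.0
    if soft_edge_voxels > 0:
        edge_w = soft_edge_voxels * density.voxel
        band = (~inside) & (dist <= margin + edge_w)
        mask[band] = 0.5 * (1.0 + np.cos(np.pi * (dist[band] - margin) / edge_w))
    return density.like(mask)


def phase_randomize(density: DensityMap, limit: float, seed: int) -> DensityMap:
    """Replace Fourier phases beyond `limit` (A) with uniform random phases,
    preserving per-voxel amplitudes and Hermitian symmetry (the randomized
    phases are taken from the transform of a real random field, so the output
    map is exactly real)."""
    density.require_fourier_ready()
    if limit <= 2.0 * density.voxel:
        raise ValueError("randomization limit must be beyond Nyquist resolution")
    f = np.fft.fftn(density.data.astype(np.float64))
    s = _freq_grid(density.shape, density.voxel)
    rng = np.random.default_rng(seed)
    noise = np.fft.fftn(rng.standard_normal(density.shape))
    beyond = s > 1.0 / limit
    amp = np.abs(f)
    nz = np.abs(noise) > 1e-300
    randomized = np.where(nz, amp * noise / np.where(nz, np.abs(noise), 1.0), 0.0)
    f = np.where(beyond, randomized, f)
    return density.like(np.real(np.fft.ifftn(f)))


def fsc(map1: DensityMap, map2: DensityMap, min_shell_count: int = 10) -> FSCCurve:
    """Fourier shell correlation between two maps on identical grids."""
    if map1.shape != map2.shape or map1.voxel != map2.voxel:
        raise ValueError("FSC requires identical grids")
    map1.require_fourier_ready()
    f1 = np.fft.fftn(map1.data.astype(np.float64))
    f2 = np.fft.fftn(map2.data.astype(np.float64))
    idx, dstep = _shell_index(map1.shape, map1.voxel, min_shell_count)
    sel = idx >= 0
    labels = idx[sel]
    nshell = labels.max() + 1
    num = np.bincount(labels, weights=np.real(f1 * np.conj(f2))[sel], minlength=nshell)
    d1 = np.bincount(labels, weights=(np.abs(f1) ** 2)[sel], minlength=nshell)
    d2 = np.bincount(labels, weights=(np.abs(f2) ** 2)[sel], minlength=nshell)
    counts = np.bincount(labels, minlength=nshell)
    keep = counts > 0
    keep[0] = False  # drop the DC shell
    denom = np.sqrt(d1[keep] * d2[keep])
    vals = np.where(denom > 0, num[keep] / np.where(denom > 0, denom, 1.0), 0.0)
    shells = np.nonzero(keep)[0]
    return FSCCurve(shells * dstep, np.clip(vals, -1.0, 1.0), counts[keep])


def fsc_true(
    fsc_masked: FSCCurve,
    fsc_randomized: FSCCurve,
    limit: float,
    buffer_shells: int = 1,
) -> FSCCurve:
    """Correct a masked FSC curve for mask-induced correlation.

    Beyond the phase-randomization limit (plus a one-shell buffer to avoid the
    discontinuity at the limit) the corrected value is
    (F_t - F_n) / (1 - F_n); at or below the limit the masked value is kept.
    Shells where F_n = 1 are undefined and reported as NaN.
    """
    if fsc_masked.freqs.shape != fsc_randomized.freqs.shape or not np.allclose(
        fsc_masked.freqs, fsc_randomized.freqs
    ):
        raise ValueError("curves must share identical shells")
    ft = fsc_masked.values
    fn = fsc_randomized.values
    out = ft.copy()
    beyond = fsc_masked.freqs > 1.0 / limit
    if beyond.any():
        first = int(np.argmax(beyond)) + buffer_shells
        corrected = np.full_like(ft, np.nan)
        ok = np.abs(1.0 - fn) > 1e-12
        corrected[ok] = (ft[ok] - fn[ok]) / (1.0 - fn[ok])
        sl = slice(first, None)
        out[sl] = corrected[sl]
    finite = np.isfinite(out)
    out[finite] = np.clip(out[finite], -1.0, 1.0)
    return FSCCurve(fsc_masked.freqs, out, fsc_masked.counts)


def resolution_at_threshold(
    curve: FSCCurve, threshold: float
) -> tuple[float, bool]:
    """Resolution (A) at the first downward threshold crossing.

    Linearly interpolates between shell centers.  Returns (resolution,
    crossed); when the curve never drops below the threshold the Nyquist
    resolution of the last shell is returned with crossed=False.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    freqs, vals = curve.freqs, curve.values
    if freqs.size == 0:
        raise ValueError("empty FSC curve")
    finite = np.isfinite(vals)
    freqs, vals = freqs[finite], vals[finite]
    for i in range(1, len(vals)):
        if vals[i - 1] >= threshold > vals[i]:
            frac = (vals[i - 1] - threshold) / (vals[i - 1] - vals[i])
            s_cross = freqs[i - 1] + frac * (freqs[i] - freqs[i - 1])
            return 1.0 / s_cross, True
    return 1.0 / freqs[-1], False


def model_map_agreement(
    model, density: DensityMap, limit: float = 11.0
) -> float:
    """Normalized Fourier-coefficient correlation between the map simulated
    from `model` (on the map's own grid) and `density`, over all frequencies
    up to 1/limit.  This is the agreement term used to keep flexibly modeled
    regions inside the experimental envelope, as a score."""
    sim = simulate_map(
        model,
        voxel=density.voxel,
        resolution=max(limit, 2.0 * density.voxel),
        shape=density.shape,
        origin=density.origin,
    )
    f1 = np.fft.fftn(sim.data.astype(np.float64))
    f2 = np.fft.fftn(density.data.astype(np.float64))
    s = _freq_grid(density.shape, density.voxel)
    sel = (s <= 1.0 / limit) & (s > 0)
    num = float(np.real(np.sum(f1[sel] * np.conj(f2[sel]))))
    den = float(
        np.sqrt(np.sum(np.abs(f1[sel]) ** 2) * np.sum(np.abs(f2[sel]) ** 2))
    )
    return num / den if den > 0 else 0.0
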