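"""Fourier measurement model for undersampled Cartesian MRI.

The scanner acquires samples of the 2-D Fourier transform of the image
(k-space).  Accelerated acquisition keeps only M < N locations chosen by a
binary mask U, giving measurements

    y = U F x + eta,

with F the *unitary* 2-D DFT (so F* F = I and U* U is an orthogonal
projector on the k-space grid) and eta i.i.d. circularly symmetric complex
Gaussian noise.  Masks use the centered (zero-frequency-at-grid-center)
layout for geometry; the shift to NumPy's FFT layout is internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceData",
    "generate_mask",
    "measure",
    "zero_fill_adjoint",
    "sigma_sq_from_noise",
]


@dataclass(frozen=True)
class SamplingMask:
    """Binary k-space sampling pattern on the full N1 x N2 grid.

    ``grid`` uses the centered layout (DC at (N1//2, N2//2)).  Sample
    ordering for the measurement vector is row-major over True entries of
    this centered grid.
    """

    grid: np.ndarray  # bool, shape (N1, N2), centered layout
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", g)
        if g.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.n_samples == 0:
            raise ValueError("mask must sample at least one location")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_samples(self) -> int:
        return int(self.grid.sum())

    @property
    def sampling_fraction(self) -> float:
        return self.n_samples / self.grid.size


@dataclass
class KSpaceData:
    """Sampled k-space measurements tied to their mask.

    ``samples`` holds the M complex values in the mask's sample ordering;
    ``noise_sigma`` is the per-component (real/imag) noise standard
    deviation used in simulation, kept for constraint-level bookkeeping.
    """

    samples: np.ndarray
    mask: SamplingMask
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.complex128).ravel()
        if self.samples.size != self.mask.n_samples:
            raise ValueError(
                f"samples length {self.samples.size} != mask M = {self.mask.n_samples}"
            )
        if not np.all(np.isfinite(self.samples.view(np.float64))):
            raise ValueError("non-finite k-space samples")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _vd_weights(shape, exponent: float) -> np.ndarray:
    """Polynomially decaying sampling weights vs distance from k-space center."""
    n1, n2 = shape
    i = np.arange(n1) - n1 // 2
    j = np.arange(n2) - n2 // 2
    # normalized radius in [0, ~1]
    r = np.sqrt(
        (i[:, None] / max(n1 // 2, 1)) ** 2 + (j[None, :] / max(n2 // 2, 1)) ** 2
    )
    w = np.clip(1.0 - r / np.sqrt(2.0), 0.0, None) ** exponent
    return w + 1e-4  # floor keeps every location reachable at high fractions


def generate_mask(
    shape,
    sampling_fraction: float,
    pattern: str = "variable_density_2d",
    center_fraction: float = 0.08,
    density_exponent: float = 4.0,
    seed: int | None = 0,
) -> SamplingMask:
    """Generate a binary Cartesian undersampling mask.

    Parameters
    ----------
    shape : (N1, N2) k-space grid shape.
    sampling_fraction : fraction of locations sampled, in (0, 1]; exactly
        ``round(sampling_fraction * N)`` locations are set.
    pattern : 'variable_density_2d' (random with polynomial density decay and
        a fully sampled center block), 'uniform_random', or 'full'.
    center_fraction : side fraction of the fully sampled central calibration
        block (variable-density pattern only).
    density_exponent : polynomial decay exponent of the sampling density.
    seed : RNG seed; identical seeds give identical masks.
    """
    n1, n2 = (int(s) for s in shape)
    N = n1 * n2
    if not 0.0 < sampling_fraction <= 1.0:
        raise ValueError("sampling_fraction must be in (0, 1]")
    m_target = int(round(sampling_fraction * N))
    m_target = max(m_target, 1)
    meta = {
        "pattern": pattern,
        "sampling_fraction": sampling_fraction,
        "center_fraction": center_fraction,
        "density_exponent": density_exponent,
        "seed": seed,
    }

    if pattern == "full" or m_target == N:
        if m_target != N:
            raise ValueError("pattern 'full' requires sampling_fraction = 1")
        return SamplingMask(np.ones((n1, n2), dtype=bool), meta)

    rng = np.random.default_rng(seed)
    grid = np.zeros((n1, n2), dtype=bool)

    if pattern == "uniform_random":
        idx = rng.choice(N, size=m_target, replace=False)
        grid.flat[idx] = True
    elif pattern == "variable_density_2d":
        c1 = max(int(round(center_fraction * n1)), 1)
        c2 = max(int(round(center_fraction * n2)), 1)
        r1 = slice(n1 // 2 - c1 // 2, n1 // 2 - c1 // 2 + c1)
        r2 = slice(n2 // 2 - c2 // 2, n2 // 2 - c2 // 2 + c2)
        grid[r1, r2] = True
        n_center = int(grid.sum())
        if m_target < n_center:
            raise ValueError(
                f"requested {m_target} samples but the fully sampled center "
                f"block already holds {n_center}; lower center_fraction"
            )
        w = _vd_weights((n1, n2), density_exponent).ravel()
        w[grid.ravel()] = 0.0
        remaining = m_target - n_center
        if remaining > 0:
            idx = rng.choice(N, size=remaining, replace=False, p=w / w.sum())
            grid.flat[idx] = True
    else:
        raise ValueError(f"unknown sampling pattern {pattern!r}")

    assert int(grid.sum()) == m_target
    return SamplingMask(grid, meta)


def _fft_centered(x: np.ndarray) -> np.ndarray:
    """Unitary 2-D DFT, output in centered layout."""
    return np.fft.fftshift(np.fft.fft2(x, norm="ortho"))


def _ifft_centered(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_fft_centered`."""
    return np.fft.ifft2(np.fft.ifftshift(k), norm="ortho")


def measure(
    x: np.ndarray,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> KSpaceData:
    """Simulate y = U F x + eta at the masked k-space locations."""
    x = np.asarray(x)
    if x.shape != mask.shape:
        raise ValueError(f"image shape {x.shape} != mask shape {mask.shape}")
    k = _fft_centered(np.ascontiguousarray(x, dtype=np.complex128))
    y = k[mask.grid]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sigma * (
            rng.standard_normal(y.size) + 1j * rng.standard_normal(y.size)
        )
    return KSpaceData(y, mask, noise_sigma=float(noise_sigma))


def mask_forward(x: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Noiseless forward operator U F applied to an image (vector of length M)."""
    return _fft_centered(x)[mask.grid]


def mask_adjoint(samples: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Adjoint F* U*: zero-fill the sample vector onto the grid and invert."""
    k = np.zeros(mask.shape, dtype=np.complex128)
    k[mask.grid] = np.asarray(samples, dtype=np.complex128).ravel()
    return _ifft_centered(k)


def zero_fill_adjoint(kdata: KSpaceData) -> np.ndarray:
    """Zero-filled reconstruction F* U* y — the standard baseline/warm start."""
    return mask_adjoint(kdata.samples, kdata.mask)


def sigma_sq_from_noise(M: int, noise_sigma: float, slack: float = 0.05) -> float:
    """Constraint level sigma^2 for a given simulated noise level.

    E||eta||^2 = 2 M noise_sigma^2 for circular complex Gaussian noise; a
    small relative slack keeps the constraint feasible for typical draws.
    """
    return 2.0 * M * noise_sigma**2 * (1.0 + slack)
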