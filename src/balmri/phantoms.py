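"""Synthetic complex-valued phantoms and ready-made undersampling fixtures.

MR images are piecewise smooth: organs and fluid compartments produce
regions of slowly varying intensity separated by sharp boundaries, which is
the source of wavelet-domain compressibility that sparse reconstruction
relies on.  The generators here produce such images with an optional smooth
random phase (off-resonance / coil phase surrogate), normalized to magnitude
in [0, 1]:

* ``shepp_logan`` — the classical head phantom (resampled to the requested
  grid).
* ``piecewise_smooth_brain`` — random nested ellipses over a smooth
  low-order intensity ramp, loosely emulating anatomical contrast.
* ``water_phantom_disks`` — a grid of uniform disks, as in QA phantoms.

All outputs are bit-reproducible from (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .kspace import KSpaceData, SamplingMask, generate_mask, measure

__all__ = ["PhantomSpec", "make_phantom", "make_fixture", "save_fixture", "load_fixture"]

PHANTOM_KINDS = ("shepp_logan", "piecewise_smooth_brain", "water_phantom_disks")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.

    contrast_range rescales the magnitude inside [0, 1]; edge_density scales
    the number of random structures for the brain-like phantom and the disk
    count for the disk phantom; phase_model is 'zero' (real image) or
    'smooth_random' (low-frequency random phase).
    """

    kind: str = "shepp_logan"
    shape: tuple[int, int] = (64, 64)
    contrast_range: tuple[float, float] = (0.0, 1.0)
    edge_density: float = 1.0
    phase_model: str = "zero"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.phase_model not in ("zero", "smooth_random"):
            raise ValueError(f"unknown phase model {self.phase_model!r}")
        lo, hi = self.contrast_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("contrast_range must satisfy 0 <= lo < hi <= 1")


def _grid(shape):
    n1, n2 = shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, n1), np.linspace(-1, 1, n2), indexing="ij")
    return yy, xx


def _magnitude(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n1, n2 = spec.shape
    if spec.kind == "shepp_logan":
        img = resize(shepp_logan_phantom(), (n1, n2), anti_aliasing=True)
    elif spec.kind == "piecewise_smooth_brain":
        yy, xx = _grid(spec.shape)
        # smooth ramp background + skull-like outer ellipse + random inner ellipses
        img = 0.1 + 0.05 * (xx + 0.5 * yy)
        outer = (xx / 0.85) ** 2 + (yy / 0.95) ** 2 <= 1.0
        img = np.where(outer, img + 0.55, 0.0)
        n_ell = max(int(round(6 * spec.edge_density)), 1)
        for _ in range(n_ell):
            cx, cy = rng.uniform(-0.5, 0.5, 2)
            ax_, ay = rng.uniform(0.08, 0.35, 2)
            th = rng.uniform(0, np.pi)
            amp = rng.uniform(-0.35, 0.35)
            xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
            yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
            inside = (xr / ax_) ** 2 + (yr / ay) ** 2 <= 1.0
            # smooth intensity ramp inside each structure keeps it piecewise
            # smooth rather than piecewise constant
            ramp = 1.0 + 0.3 * xr
            img = np.where(inside & outer, img + amp * ramp, img)
        img = np.clip(img, 0.0, None)
    else:  # water_phantom_disks
        yy, xx = _grid(spec.shape)
        img = np.zeros(spec.shape)
        k = max(int(round(3 * spec.edge_density)), 1)
        centers = np.linspace(-0.6, 0.6, k)
        r = min(0.5 / k, 0.45)
        for cy in centers:
            for cx in centers:
                img += 0.9 * (((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2)
        img += 0.05

    mx = img.max()
    if mx > 0:
        img = img / mx
    lo, hi = spec.contrast_range
    return lo + (hi - lo) * img


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a complex piecewise-smooth phantom per the spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    mag = _magnitude(spec, rng)
    if spec.phase_model == "zero":
        return mag.astype(np.complex128)
    # low-frequency random phase field, +-~0.5 rad
    phase = gaussian_filter(rng.standard_normal(spec.shape), sigma=min(spec.shape) / 8)
    phase = 0.5 * phase / max(np.abs(phase).max(), 1e-12)
    return mag * np.exp(1j * phase)


def make_fixture(
    spec: PhantomSpec,
    sampling_fraction: float = 0.4,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pattern: str = "variable_density_2d",
    out_dir: str | Path | None = None,
) -> tuple[np.ndarray, SamplingMask, KSpaceData]:
    """Phantom + mask + measured k-space, optionally persisted with a manifest.

    The mask seed and the noise seed are derived from ``seed`` so one integer
    reproduces the whole fixture.
    """
    if sampling_fraction >= 1.0:
        pattern = "full"
    x = make_phantom(spec)
    mask = generate_mask(spec.shape, sampling_fraction, pattern=pattern, seed=seed)
    y = measure(x, mask, noise_sigma=noise_sigma, seed=seed + 1)
    if out_dir is not None:
        save_fixture(Path(out_dir), x, mask, y, spec, seed)
    return x, mask, y


def save_fixture(out_dir, x, mask, y, spec: PhantomSpec | None = None, seed: int | None = None):
    """Persist a fixture as an HDF5 container + JSON manifest (+ mask PNG)."""
    import h5py
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with h5py.File(out_dir / "fixture.h5", "w") as f:
        f.create_dataset("phantom_real", data=x.real)
        f.create_dataset("phantom_imag", data=x.imag)
        f.create_dataset("mask", data=mask.grid.astype(np.uint8))
        f.create_dataset("samples_real", data=y.samples.real)
        f.create_dataset("samples_imag", data=y.samples.imag)
    iio.imwrite(out_dir / "mask.png", (mask.grid * np.uint8(255)))
    manifest = {
        "spec": None if spec is None else asdict(spec),
        "seed": seed,
        "noise_sigma": y.noise_sigma,
        "mask_meta": mask.meta,
        "n_samples": mask.n_samples,
        "shape": list(mask.shape),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_fixture(out_dir) -> tuple[np.ndarray, SamplingMask, KSpaceData]:
    """Inverse of :func:`save_fixture` (arrays round-trip exactly)."""
    import h5py

    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    with h5py.File(out_dir / "fixture.h5", "r") as f:
        x = f["phantom_real"][:] + 1j * f["phantom_imag"][:]
        grid = f["mask"][:].astype(bool)
        samples = f["samples_real"][:] + 1j * f["samples_imag"][:]
    mask = SamplingMask(grid, manifest.get("mask_meta", {}))
    y = KSpaceData(samples, mask, noise_sigma=manifest.get("noise_sigma", 0.0))
    return x, mask, y
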