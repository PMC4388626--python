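"""Parseval tight-frame analysis/synthesis operators.

A tight frame is a linear map ``Psi`` from an N-pixel complex image to a
vector of D >= N coefficients with ``Psi* Psi = I`` (perfect reconstruction
through the adjoint) and, in the Parseval-normalized case required here,
``||Psi x|| = ||x||``.  The composite ``Psi Psi*`` is then the orthogonal
projector onto the range of ``Psi``; it equals the identity only when the
frame is an orthogonal basis (D = N).

Three constructions are provided:

* :func:`make_sidwt_frame` — shift-invariant (undecimated) separable wavelet
  frame, redundancy ``3*levels + 1``, built from orthonormal wavelet filters
  applied with periodic boundary handling in the Fourier domain.
* :func:`make_orthogonal_dwt_frame` — critically sampled orthogonal wavelet
  basis (D = N), via PyWavelets with periodization boundaries.
* :func:`make_tidct_frame` — translation-invariant patch DCT, redundancy
  ``patch_size**2``.

Coefficients are exposed to callers as flat complex vectors; the subband
layout (subband-major, row-major within each subband) is an internal,
self-consistent convention.

Every constructor verifies the Parseval identity numerically and refuses to
return a frame that fails it, because the solvers' closed-form coefficient
update is exact only for Parseval frames.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.fft import dctn, idctn

__all__ = [
    "FrameOperator",
    "make_sidwt_frame",
    "make_orthogonal_dwt_frame",
    "make_tidct_frame",
    "make_frame",
    "analysis",
    "synthesis",
    "range_projection",
]

_TIGHTNESS_TOL = 1e-10


class FrameError(ValueError):
    """Raised for invalid frame configurations or contract violations."""


class FrameOperator:
    """Abstract paired analysis/synthesis operator of a Parseval tight frame.

    Attributes
    ----------
    shape : tuple of int
        Image grid shape (N1, N2).
    n_pixels : int
        N = N1 * N2.
    n_coefficients : int
        D, the length of the coefficient vector; D >= N.
    redundancy : float
        D / N.
    is_orthogonal : bool
        True when D = N and the frame is a basis (analysis inverts synthesis
        from both sides).
    """

    name = "frame"

    def __init__(self, shape: tuple[int, int]):
        if len(shape) != 2 or any(s < 2 for s in shape):
            raise FrameError(f"expected a 2-D image shape, got {shape}")
        self.shape = tuple(int(s) for s in shape)
        self.n_pixels = int(np.prod(self.shape))

    # -- subclass surface -------------------------------------------------
    def _analysis(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _synthesis(self, a: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- public API -------------------------------------------------------
    @property
    def redundancy(self) -> float:
        return self.n_coefficients / self.n_pixels

    @property
    def is_orthogonal(self) -> bool:
        return self.n_coefficients == self.n_pixels

    def analysis(self, x: np.ndarray) -> np.ndarray:
        """Apply the analysis map Psi: image -> flat coefficient vector."""
        x = np.asarray(x)
        if x.shape != self.shape:
            raise FrameError(
                f"image shape {x.shape} does not match frame shape {self.shape}"
            )
        return self._analysis(np.ascontiguousarray(x, dtype=np.complex128))

    def synthesis(self, a: np.ndarray) -> np.ndarray:
        """Apply the synthesis map Psi* (adjoint): coefficients -> image."""
        a = np.asarray(a).ravel()
        if a.size != self.n_coefficients:
            raise FrameError(
                f"coefficient length {a.size} != D = {self.n_coefficients}"
            )
        return self._synthesis(np.ascontiguousarray(a, dtype=np.complex128))

    def range_projection(self, a: np.ndarray) -> np.ndarray:
        """Orthogonal projection Psi Psi* onto the range of the analysis map."""
        return self.analysis(self.synthesis(a))

    def _verify_tightness(self, rng_seed: int = 0, n_trials: int = 3) -> None:
        """Reject non-Parseval constructions at build time."""
        rng = np.random.default_rng(rng_seed)
        for _ in range(n_trials):
            x = rng.standard_normal(self.shape) + 1j * rng.standard_normal(self.shape)
            a = self.analysis(x)
            nx = np.linalg.norm(x)
            if abs(np.linalg.norm(a) - nx) / nx > _TIGHTNESS_TOL:
                raise FrameError(
                    f"{self.name}: frame is not Parseval tight "
                    "(||Psi x|| != ||x||); construction rejected"
                )
            xr = self.synthesis(a)
            if np.linalg.norm(xr - x) / nx > _TIGHTNESS_TOL:
                raise FrameError(
                    f"{self.name}: perfect reconstruction Psi* Psi = I failed"
                )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<{type(self).__name__} {self.name} shape={self.shape} "
            f"D={self.n_coefficients} redundancy={self.redundancy:g}>"
        )


class SIDWTFrame(FrameOperator):
    """Shift-invariant (undecimated, a-trous) separable 2-D wavelet frame.

    Filtering is performed in the Fourier domain with periodic boundary
    extension.  Per level the orthonormal analysis pair (h, g) is scaled by
    1/sqrt(2), so that |H|^2 + |G|^2 = 1 pointwise and the full transform is
    exactly Parseval tight.  Subbands per level: LH, HL, HH, plus one final
    approximation band — redundancy 3*levels + 1.
    """

    name = "sidwt"

    def __init__(self, shape, wavelet_name: str = "db4", levels: int = 3):
        super().__init__(shape)
        if levels < 1:
            raise FrameError("levels must be >= 1")
        for s in self.shape:
            if s % (2**levels) != 0:
                raise FrameError(
                    f"shape {shape} not divisible by 2^levels = {2**levels}"
                )
        try:
            wav = pywt.Wavelet(wavelet_name)
        except ValueError as exc:
            raise FrameError(f"unsupported wavelet {wavelet_name!r}") from exc
        if not wav.orthogonal:
            raise FrameError(
                f"wavelet {wavelet_name!r} is not orthogonal; the undecimated "
                "frame would not be Parseval tight"
            )
        self.wavelet_name = wavelet_name
        self.levels = levels
        self._transfer = self._build_transfer(wav)
        self.n_coefficients = len(self._transfer) * self.n_pixels
        self._verify_tightness()

    def _build_transfer(self, wav: pywt.Wavelet) -> list[np.ndarray]:
        """2-D transfer functions T_b with sum_b |T_b|^2 = 1 pointwise."""
        h = np.asarray(wav.dec_lo, dtype=np.float64)
        g = np.asarray(wav.dec_hi, dtype=np.float64)

        def resp(filt: np.ndarray, n: int, dilation: int) -> np.ndarray:
            k = np.arange(n)
            m = np.arange(filt.size)
            # frequency response of the dilated (a-trous) filter, periodic grid
            E = np.exp(-2j * np.pi * np.outer(k, m * dilation) / n)
            return (E @ filt) / np.sqrt(2.0)

        n1, n2 = self.shape
        lo1 = np.ones(n1, dtype=np.complex128)
        lo2 = np.ones(n2, dtype=np.complex128)
        bands: list[np.ndarray] = []
        for j in range(self.levels):
            d = 2**j
            H1, G1 = resp(h, n1, d), resp(g, n1, d)
            H2, G2 = resp(h, n2, d), resp(g, n2, d)
            # detail subbands at this level (LH, HL, HH in axis-0/axis-1 order)
            bands.append(np.outer(lo1 * H1, lo2 * G2))
            bands.append(np.outer(lo1 * G1, lo2 * H2))
            bands.append(np.outer(lo1 * G1, lo2 * G2))
            lo1 = lo1 * H1
            lo2 = lo2 * H2
        bands.append(np.outer(lo1, lo2))  # final approximation
        return bands

    def _analysis(self, x):
        X = np.fft.fft2(x, norm="ortho")
        out = np.empty((len(self._transfer), *self.shape), dtype=np.complex128)
        for b, T in enumerate(self._transfer):
            out[b] = np.fft.ifft2(T * X, norm="ortho")
        return out.ravel()

    def _synthesis(self, a):
        sub = a.reshape((len(self._transfer), *self.shape))
        acc = np.zeros(self.shape, dtype=np.complex128)
        for b, T in enumerate(self._transfer):
            acc += np.conj(T) * np.fft.fft2(sub[b], norm="ortho")
        return np.fft.ifft2(acc, norm="ortho")


class OrthogonalDWTFrame(FrameOperator):
    """Critically sampled orthogonal 2-D wavelet basis (D = N).

    Wraps PyWavelets wavedec2/waverec2 with periodization boundaries, which is
    an orthonormal transform for orthogonal filters; the adjoint equals the
    inverse, so synthesis is the inverse DWT.
    """

    name = "dwt"

    def __init__(self, shape, wavelet_name: str = "db4", levels: int = 3):
        super().__init__(shape)
        if levels < 1:
            raise FrameError("levels must be >= 1")
        for s in self.shape:
            if s % (2**levels) != 0:
                raise FrameError(
                    f"shape {shape} not divisible by 2^levels = {2**levels}"
                )
        try:
            wav = pywt.Wavelet(wavelet_name)
        except ValueError as exc:
            raise FrameError(f"unsupported wavelet {wavelet_name!r}") from exc
        if not wav.orthogonal:
            raise FrameError(f"wavelet {wavelet_name!r} is not orthogonal")
        self.wavelet_name = wavelet_name
        self.levels = levels
        self.n_coefficients = self.n_pixels
        # freeze the coefficient layout once
        probe = pywt.wavedec2(
            np.zeros(self.shape, dtype=np.complex128),
            wavelet_name,
            mode="periodization",
            level=levels,
        )
        _, self._slices = pywt.coeffs_to_array(probe)
        self._verify_tightness()

    def _analysis(self, x):
        coeffs = pywt.wavedec2(
            x, self.wavelet_name, mode="periodization", level=self.levels
        )
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr.ravel()

    def _synthesis(self, a):
        arr = a.reshape(self.shape)
        coeffs = pywt.array_to_coeffs(arr, self._slices, output_format="wavedec2")
        return pywt.waverec2(coeffs, self.wavelet_name, mode="periodization")


class TIDCTFrame(FrameOperator):
    """Translation-invariant patch DCT frame.

    The image is tiled into non-overlapping patch_size x patch_size blocks and
    each block is transformed by the orthonormal 2-D DCT; this is repeated for
    every cyclic shift of the tiling grid (patch_size shifts per axis, step 1)
    and the stack is scaled by 1/sqrt(#tilings), which makes the union
    Parseval tight.  Redundancy patch_size**2.  When the patch spans the whole
    image along an axis, shifting is redundant and a single tiling is used;
    with patch_size equal to the image size the frame degenerates to the
    orthogonal 2-D DCT (D = N).
    """

    name = "tidct"

    def __init__(self, shape, patch_size: int = 8):
        super().__init__(shape)
        p = int(patch_size)
        n1, n2 = self.shape
        if p < 2 or p > n1 or p > n2 or n1 % p or n2 % p:
            raise FrameError(
                f"invalid patch size {patch_size} for image shape {shape}"
            )
        self.patch_size = p
        s1 = 1 if p == n1 else p
        s2 = 1 if p == n2 else p
        self._shifts = [(i, j) for i in range(s1) for j in range(s2)]
        self._scale = 1.0 / np.sqrt(len(self._shifts))
        self.n_coefficients = len(self._shifts) * self.n_pixels
        self._verify_tightness()

    def _blocks(self, x):
        p = self.patch_size
        n1, n2 = self.shape
        return x.reshape(n1 // p, p, n2 // p, p).transpose(0, 2, 1, 3)

    def _unblocks(self, b):
        p = self.patch_size
        n1, n2 = self.shape
        return b.transpose(0, 2, 1, 3).reshape(n1, n2)

    def _analysis(self, x):
        out = np.empty((len(self._shifts), *self.shape), dtype=np.complex128)
        for k, (i, j) in enumerate(self._shifts):
            shifted = np.roll(x, (-i, -j), axis=(0, 1))
            out[k] = self._unblocks(dctn(self._blocks(shifted), axes=(2, 3), norm="ortho"))
        return (out * self._scale).ravel()

    def _synthesis(self, a):
        sub = a.reshape((len(self._shifts), *self.shape))
        acc = np.zeros(self.shape, dtype=np.complex128)
        for k, (i, j) in enumerate(self._shifts):
            img = idctn(self._blocks(sub[k]), axes=(2, 3), norm="ortho")
            acc += np.roll(self._unblocks(img), (i, j), axis=(0, 1))
        return acc * self._scale


def make_sidwt_frame(shape, wavelet_name: str = "db4", levels: int = 3) -> SIDWTFrame:
    """Shift-invariant wavelet tight frame (default db4, 3 levels)."""
    return SIDWTFrame(shape, wavelet_name, levels)


def make_orthogonal_dwt_frame(
    shape, wavelet_name: str = "db4", levels: int = 3
) -> OrthogonalDWTFrame:
    """Orthogonal wavelet basis as a (non-redundant) frame."""
    return OrthogonalDWTFrame(shape, wavelet_name, levels)


def make_tidct_frame(shape, patch_size: int = 8) -> TIDCTFrame:
    """Translation-invariant patch-DCT tight frame."""
    return TIDCTFrame(shape, patch_size)


_FACTORIES = {
    "sidwt": make_sidwt_frame,
    "dwt": make_orthogonal_dwt_frame,
    "tidct": make_tidct_frame,
}


def make_frame(name: str, shape, **kwargs) -> FrameOperator:
    """Config-driven frame construction.

    Parameters
    ----------
    name : {'sidwt', 'dwt', 'tidct'}
    shape : image grid shape
    kwargs : wavelet_name/levels for wavelet frames, patch_size for tidct.
    """
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise FrameError(
            f"unknown frame {name!r}; choose from {sorted(_FACTORIES)}"
        ) from None
    return factory(shape, **kwargs)


# thin functional wrappers over the operator methods
def analysis(x: np.ndarray, frame: FrameOperator) -> np.ndarray:
    return frame.analysis(x)


def synthesis(a: np.ndarray, frame: FrameOperator) -> np.ndarray:
    return frame.synthesis(a)


def range_projection(a: np.ndarray, frame: FrameOperator) -> np.ndarray:
    return frame.range_projection(a)
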