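"""Reconstruction quality metric."""

from __future__ import annotations

import numpy as np

__all__ = ["rlne"]


def rlne(x_hat: np.ndarray, x_ref: np.ndarray) -> float:
    """Relative l2-norm error ||x_hat - x_ref||_2 / ||x_ref||_2.

    Computed on the complex values (not magnitudes), matching how the
    solvers operate; zero iff the images are identical.
    """
    x_hat = np.asarray(x_hat)
    x_ref = np.asarray(x_ref)
    if x_hat.shape != x_ref.shape:
        raise ValueError(f"shape mismatch: {x_hat.shape} vs {x_ref.shape}")
    ref_norm = np.linalg.norm(x_ref)
    if ref_norm == 0:
        raise ValueError("reference image has zero norm")
    return float(np.linalg.norm(x_hat - x_ref) / ref_norm)
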