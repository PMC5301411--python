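"""Centred, unitary 2-D Fourier transforms.

Single FFT convention for the whole package: origin at the array centre
``(ny//2, nx//2)`` in both image and k-space, unitary scaling. With this
convention the adjoint of the forward transform equals its inverse, which
keeps the sampled-Fourier forward operator and its adjoint exactly matched
(required by the conjugate-gradient solver).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c"]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centred unitary 2-D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho",
                    axes=(-2, -1)), axes=(-2, -1))


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Centred unitary 2-D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho",
                     axes=(-2, -1)), axes=(-2, -1))
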