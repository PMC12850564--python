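"""Centered 2D DFT helpers.

All modules share one convention: the DC sample sits at index ``N // 2`` on
each axis, both in image space and in k-space.  ``fft2c``/``ifft2c`` are the
unnormalized numpy transforms wrapped in the fftshift pair that realizes this
convention, so ``ifft2c(fft2c(x)) == x`` and Parseval reads
``sum |fft2c(x)|^2 == N^2 * sum |x|^2``.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray


def fft2c(x: NDArray) -> NDArray:
    """Centered forward 2D DFT over the last two axes (unnormalized)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    )


def ifft2c(x: NDArray) -> NDArray:
    """Centered inverse 2D DFT over the last two axes (includes 1/N^2)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    )


def centered_coords(n: int) -> NDArray[np.int64]:
    """Integer coordinates with 0 at the DC index ``n // 2``."""
    return np.arange(n) - n // 2
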