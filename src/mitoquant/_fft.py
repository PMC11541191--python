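"""Cached-OTF FFT convolution ('same' output) used by the simulator and RL."""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = ["FFTConvolver"]


class FFTConvolver:
    """Convolve many same-shaped arrays with one kernel, reusing its OTF.

    Output is the 'same' central region, i.e. the result is aligned with
    the input for an odd-shaped, centred kernel.
    """

    def __init__(
        self,
        kernel: np.ndarray,
        shape: tuple[int, ...],
        dtype: np.dtype = np.float64,
    ):
        kernel = np.asarray(kernel, dtype=dtype)
        if kernel.ndim != len(shape):
            raise ValueError("kernel and image dimensionality differ")
        self.dtype = np.dtype(dtype)
        self.shape = tuple(shape)
        self.kshape = kernel.shape
        self.fshape = tuple(
            sfft.next_fast_len(s + k - 1) for s, k in zip(shape, kernel.shape)
        )
        self._otf = sfft.rfftn(kernel, self.fshape)
        self._crop = tuple(
            slice(k // 2, k // 2 + s) for s, k in zip(shape, kernel.shape)
        )

    def convolve(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {image.shape}")
        spec = sfft.rfftn(image.astype(self.dtype, copy=False), self.fshape)
        full = sfft.irfftn(spec * self._otf, self.fshape)
        return full[self._crop]
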