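"""Reference 1-D convolution used as the oracle for conv-layer tests."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def convolve_reference(x: Sequence[float], h: Sequence[float]) -> np.ndarray:
    """Full discrete convolution, written as the literal defining sum.

    y_k = sum_{n=0}^{N-1} x_n * h_{k-n}, with h indexed from 0 at its
    first element and out-of-range h terms taken as zero, so y has
    length N + len(h) - 1.  Deliberately naive: this is the oracle the
    vectorized conv layers are checked against.
    """
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if x.size == 0 or h.size == 0:
        raise ValueError("convolve_reference requires non-empty sequences")
    n_x, n_h = x.size, h.size
    y = np.zeros(n_x + n_h - 1)
    for k in range(y.size):
        acc = 0.0
        for n in range(n_x):
            j = k - n
            if 0 <= j < n_h:
                acc += x[n] * h[j]
        y[k] = acc
    return y
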