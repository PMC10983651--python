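"""Centered moving averages shared by trajectory and spectrum smoothing.

An odd window of N samples is the plain symmetric mean over N points.  An
even window is realised as the standard centred "2xN" moving average:
N+1 points with half weight on the two extreme samples, which keeps the
filter symmetric (a linear ramp passes through unchanged) while averaging
exactly N samples' worth of mass.  Either form cancels a sinusoid whose
period divides the window span exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["centered_moving_average", "half_window"]


def half_window(window: int) -> int:
    """Half-width h of the symmetric kernel for a window of N samples."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return window // 2 if window % 2 == 0 else (window - 1) // 2


def _kernel(h: int, even: bool) -> np.ndarray:
    if h == 0:
        return np.ones(1)
    if even:
        w = np.ones(2 * h + 1)
        w[0] = w[-1] = 0.5
        return w / (2 * h)
    return np.ones(2 * h + 1) / (2 * h + 1)


def centered_moving_average(
    values: np.ndarray, window: int, edge: str = "shrink"
) -> np.ndarray:
    """Centered moving average along axis 0.

    Parameters
    ----------
    values : array, shape (n,) or (n, d)
    window : int
        Number of samples averaged (N); even windows use the half-end-weight
        centred form.
    edge : {"shrink", "trim"}
        "shrink": near the boundaries the window shrinks symmetrically to
        the samples available, so the output keeps the input length.
        "trim": only samples with a complete window are returned
        (length n - 2h); callers must trim the time grid accordingly.
    """
    x = np.asarray(values, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if edge not in ("shrink", "trim"):
        raise ValueError("edge must be 'shrink' or 'trim'")
    even = window % 2 == 0
    h = half_window(window)
    if n <= 2 * h:
        if edge == "trim":
            raise ValueError(f"window {window} too long for {n} samples with edge='trim'")
        # whole record shorter than the window: every sample uses a shrunk kernel
        out = np.empty_like(x)
        for i in range(n):
            hi = min(i, n - 1 - i)
            k = _kernel(hi, even and hi > 0)
            out[i] = k @ x[i - hi : i + hi + 1]
        return out[:, 0] if squeeze else out

    k = _kernel(h, even)
    interior = np.empty((n - 2 * h, x.shape[1]))
    for j in range(x.shape[1]):
        interior[:, j] = np.convolve(x[:, j], k[::-1], mode="valid")
    if edge == "trim":
        return interior[:, 0] if squeeze else interior

    out = np.empty_like(x)
    out[h : n - h] = interior
    for i in range(h):
        hi = i
        ke = _kernel(hi, even and hi > 0)
        out[i] = ke @ x[: 2 * hi + 1]
        ke2 = ke  # same shrunk width at the mirrored end
        out[n - 1 - i] = ke2 @ x[n - 1 - 2 * hi :]
    return out[:, 0] if squeeze else out
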