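"""Causal Savitzky-Golay smoothing of the recognised-baseline stream.

The per-minute raw baseline predictions carry recognition jitter that would
make threshold comparisons chatter.  A Savitzky-Golay filter fits a low-order
polynomial to a trailing window of raw values and evaluates it at the *newest*
point.  This endpoint (causal) variant deliberately differs from the textbook
centred filter: a controller cannot use future data, so the fit is evaluated
at the trailing window's right edge.  Endpoint evaluation preserves the
filter's defining property — polynomials up to ``poly_order`` pass through
unchanged — at the cost of less attenuation than the centred form.

During warm-up (fewer samples than ``window_length``) the running mean of the
buffer is returned as a documented fallback.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy.signal import savgol_coeffs

__all__ = ["CausalSavitzkyGolay", "smooth_update"]


class CausalSavitzkyGolay:
    """Streaming endpoint Savitzky-Golay filter.

    Parameters
    ----------
    window_length
        Number of trailing points fitted (odd, default 15 — with one raw
        baseline per minute, a quarter hour of history: long enough to
        suppress minute-scale recognition jitter, short enough to track
        metabolic drifts over tens of minutes).
    poly_order
        Order of the fitted polynomial (default 2); must be < window_length.
    """

    def __init__(self, window_length: int = 15, poly_order: int = 2) -> None:
        if window_length % 2 != 1 or window_length < 3:
            raise ValueError("window_length must be odd and >= 3")
        if not 0 <= poly_order < window_length:
            raise ValueError("poly_order must satisfy 0 <= poly_order < window_length")
        self.window_length = window_length
        self.poly_order = poly_order
        # coefficients for evaluating the LSQ polynomial at the newest sample
        self.coeffs = savgol_coeffs(
            window_length, poly_order, pos=window_length - 1, use="dot"
        )
        self.buffer: deque[float] = deque(maxlen=window_length)

    def update(self, raw_value: float) -> float:
        """Ingest one raw baseline value and return the smoothed estimate."""
        raw_value = float(raw_value)
        if not math.isfinite(raw_value):
            raise ValueError("raw baseline value must be finite")
        self.buffer.append(raw_value)
        if len(self.buffer) < self.window_length:
            return float(np.mean(self.buffer))
        return float(np.dot(self.coeffs, np.asarray(self.buffer)))

    def reset(self) -> None:
        self.buffer.clear()


def smooth_update(state: CausalSavitzkyGolay, raw_baseline: float) -> float:
    """Functional alias for :meth:`CausalSavitzkyGolay.update`."""
    return state.update(raw_baseline)
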