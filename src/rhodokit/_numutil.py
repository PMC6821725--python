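"""Small shared numerics."""

from __future__ import annotations

import numpy as np

__all__ = ["parabolic_peak"]


def parabolic_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Peak position by a 3-point parabola around the grid maximum.

    Returns ``(x_peak, y_peak, at_boundary)``.  When the maximum sits on the
    first or last grid point no interpolation is possible; the boundary value
    is returned with ``at_boundary=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to locate a peak")
    i = int(np.argmax(y))
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i]), True
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    # vertex of the Lagrange parabola through the three points
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if a == 0:
        return float(x1), float(y1), False
    xp = -b / (2 * a)
    c = y0 - a * x0 ** 2 - b * x0
    yp = a * xp ** 2 + b * xp + c
    return float(xp), float(yp), False
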