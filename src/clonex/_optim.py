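"""Bounded scalar maximisation helpers shared by the likelihood-ratio tests.

Two flavours are provided: a vectorised golden-section search for the
placement log-likelihood, whose objective is concave in the shift (a sum of
log-logistic terms), and a grid-scan-plus-Brent refinement for the occurrence
and combined objectives, where concavity is not guaranteed analytically.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0
_INVPHI2 = (3.0 - np.sqrt(5.0)) / 2.0


def golden_max(f, lo: float, hi: float, shape, tol: float = 1e-8):
    """Maximise a batch of unimodal scalar functions by golden-section search.

    Parameters
    ----------
    f : callable
        Maps an array of abscissae (one per batch row, shape ``shape``) to
        objective values of the same shape.
    lo, hi : float
        Common search interval for every row.
    shape : tuple
        Batch shape.
    tol : float
        Final interval width.

    Returns
    -------
    (x, fx) : arrays of shape ``shape`` with the per-row argmax and maximum.
    """
    a = np.full(shape, float(lo))
    b = np.full(shape, float(hi))
    h = b - a
    c = a + _INVPHI2 * h
    d = a + _INVPHI * h
    fc = f(c)
    fd = f(d)
    span = float(hi) - float(lo)
    if span <= tol:
        xm = 0.5 * (a + b)
        return xm, f(xm)
    n_iter = int(np.ceil(np.log(tol / span) / np.log(_INVPHI)))
    for _ in range(n_iter):
        left = fc > fd  # maximum lies in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        h = b - a
        c_new = a + _INVPHI2 * h
        d_new = a + _INVPHI * h
        x = np.where(left, c_new, d_new)
        fx = f(x)
        # golden property: the surviving interior point keeps its value
        fc, fd = np.where(left, fx, fd), np.where(left, fc, fx)
        c, d = c_new, d_new
    xm = 0.5 * (a + b)
    return xm, f(xm)


def grid_refine_max(f, lo: float, hi: float, n_grid: int = 41):
    """Maximise a scalar function by a coarse grid scan with local refinement.

    Robust to mild multi-modality; the Brent refinement is restricted to the
    grid bracket around the best grid point.
    """
    xs = np.linspace(lo, hi, n_grid)
    ys = np.array([f(x) for x in xs])
    i = int(np.argmax(ys))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda x: -f(x), bounds=(a, b), method="bounded",
                          options={"xatol": 1e-9})
    if -res.fun >= ys[i]:
        return float(res.x), float(-res.fun)
    return float(xs[i]), float(ys[i])
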