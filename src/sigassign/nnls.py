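"""Nonnegative least squares with relative reconstruction error.

The whole assignment engine reduces to repeated solves of

    min_{a >= 0} || v - S a ||_2^2

scored by the relative error eps = ||v - S a||^2 / ||v||^2. The solver is
the Lawson-Hanson active-set method (scipy.optimize.nnls).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _lawson_hanson

__all__ = ["calc_nnls"]


def calc_nnls(v: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    """Solve min_{a>=0} ||v - S a||^2 and return (eps, a).

    Parameters
    ----------
    v : (xi,) nonnegative spectrum with ||v|| > 0.
    S : (xi, q) matrix of signature columns, q >= 1.

    Returns
    -------
    eps : ||v - S a||^2 / ||v||^2. Always <= 1 + roundoff, since a = 0 is
        feasible.
    a : the nonnegative minimizer (real-valued).
    """
    v = np.asarray(v, dtype=float)
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if v.ndim != 1 or S.ndim != 2 or S.shape[0] != v.shape[0]:
        raise ValueError(f"dimension mismatch: v {v.shape}, S {S.shape}")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(S))):
        raise ValueError("non-finite inputs")
    vv = float(v @ v)
    if vv <= 0:
        raise ValueError("zero spectrum: ||v|| must be positive")
    a, rnorm = _lawson_hanson(S, v)
    return rnorm * rnorm / vv, a
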