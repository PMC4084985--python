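"""Cyclic cubic regression splines.

A cyclic cubic regression spline is the natural interpolating cubic through
function values at k knots spanning one period, constrained so that the value
and first two derivatives match at the period boundary. The basis is
parameterized directly by the function values at the k-1 distinct knots; the
roughness penalty is the integrated squared second derivative, which for this
family has the closed form b' D' B^{-1} D b with B and D cyclically banded.
"""

from __future__ import annotations

import numpy as np


def cyclic_knots(period: float, n_knots: int) -> np.ndarray:
    """Evenly spaced knots over [0, period]; first and last knot coincide cyclically."""
    if n_knots < 4:
        raise ValueError("cyclic cubic spline needs at least 4 knots")
    return np.linspace(0.0, period, n_knots)


def _cyclic_BD(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Banded matrices linking knot values to knot second derivatives.

    With h_i the knot spacings (cyclic), B g = D b where b holds the function
    values and g the second derivatives at the k-1 distinct knots.
    """
    h = np.diff(knots)  # length k-1, h[i] = gap following distinct knot i
    m = len(h)
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for i in range(m):
        ip = (i + 1) % m
        hm = h[i - 1]  # gap preceding knot i (wraps for i=0)
        B[i, i] = (hm + h[i]) / 3.0
        B[i, ip] += h[i] / 6.0
        B[ip, i] += h[i] / 6.0
        D[i, i] = -(1.0 / hm + 1.0 / h[i])
        D[i, ip] += 1.0 / h[i]
        D[ip, i] += 1.0 / h[i]
    return B, D


def cyclic_basis(x, period: float, n_knots: int) -> tuple[np.ndarray, np.ndarray]:
    """Design and penalty matrices for a cyclic cubic regression spline.

    Parameters
    ----------
    x : array-like
        Covariate values; wrapped into [0, period).
    period : float
        Cycle length (365.25 for day of year, 360 for lunar phase).
    n_knots : int
        Number of knots including the duplicated end knot; the basis has
        ``n_knots - 1`` columns.

    Returns
    -------
    X : (n, k-1) ndarray
        Rows evaluate the spline at x given knot values; rows for x and
        x + period are identical.
    S : (k-1, k-1) ndarray
        Second-derivative roughness penalty, positive semi-definite with the
        constant function in its null space.
    """
    x = np.asarray(x, dtype=float) % period
    knots = cyclic_knots(period, n_knots)
    B, D = _cyclic_BD(knots)
    BinvD = np.linalg.solve(B, D)
    S = D.T @ BinvD
    S = (S + S.T) / 2.0

    m = n_knots - 1
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, m - 1)
    h = np.diff(knots)[j]
    xl = knots[j]
    xr = knots[j + 1]
    # natural-cubic interpolation weights on values (a) and curvatures (c)
    a_minus = (xr - x) / h
    a_plus = (x - xl) / h
    c_minus = ((xr - x) ** 3 / h - h * (xr - x)) / 6.0
    c_plus = ((x - xl) ** 3 / h - h * (x - xl)) / 6.0

    n = len(x)
    A = np.zeros((n, m))
    C = np.zeros((n, m))
    rows = np.arange(n)
    A[rows, j] = a_minus
    A[rows, (j + 1) % m] += a_plus
    C[rows, j] = c_minus
    C[rows, (j + 1) % m] += c_plus
    X = A + C @ BinvD
    return X, S


def center_constraint(X: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absorb the sum-to-zero identifiability constraint 1'Xb = 0.

    Returns the reparameterized design and penalty plus the (k-1, k-2)
    transform Z mapping constrained coefficients back to knot values. After
    the constraint the penalty is full rank (the constant null space is gone),
    so the smoothing parameter fully controls shrinkage to zero.
    """
    c = X.sum(axis=0)[:, None]
    q, _ = np.linalg.qr(c, mode="complete")
    Z = q[:, 1:]
    return X @ Z, Z.T @ S @ Z, Z
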