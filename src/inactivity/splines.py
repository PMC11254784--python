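"""Natural cubic spline basis for smooth age patterns.

Prevalence of insufficient activity varies smoothly but non-linearly with
age (roughly flat or gently rising through mid-life, steeper after about
age 60).  The model captures this with a natural cubic spline in age:
piecewise cubic between knots, with continuous second derivatives, and
constrained to be *linear* beyond the boundary knots so that the sparse
oldest/youngest ages cannot produce wild cubic extrapolation.

The basis here is the classic truncated-power natural basis.  With interior
knots k_1 < ... < k_m and boundary knots b_lo < b_hi, the full knot sequence
is xi_1 = b_lo, xi_2 = k_1, ..., xi_{m+1} = k_m, xi_{m+2} = b_hi and

    d_j(x) = [ (x - xi_j)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_j)

    N_1(x) = x,   N_{j+1}(x) = d_j(x) - d_{K-1}(x)   (j = 1..K-2)

which yields m + 1 basis columns (an intercept is supplied by the model).
Ages are mapped to [0, 1] over the boundary interval before the powers are
taken, so all columns are O(1) and coefficients on them are comparable to
the other probit-scale terms.
"""

from __future__ import annotations

import numpy as np


def natural_cubic_basis(
    age: np.ndarray | float,
    knots: tuple[float, ...] = (30.0, 60.0),
    boundary: tuple[float, float] = (18.0, 85.0),
) -> np.ndarray:
    """Evaluate the natural cubic spline basis at one or more ages.

    Parameters
    ----------
    age
        Age(s) in years.  Values outside the boundary knots are clamped to
        the nearest boundary.
    knots
        Interior knot ages, strictly inside the boundary interval.
    boundary
        (low, high) boundary knot ages.

    Returns
    -------
    ndarray of shape ``(n, len(knots) + 1)`` (or ``(len(knots) + 1,)`` for
    scalar input).
    """
    lo, hi = float(boundary[0]), float(boundary[1])
    if not lo < hi:
        raise ValueError(f"boundary knots must be ordered, got {boundary}")
    ks = tuple(float(k) for k in knots)
    if any(not lo < k < hi for k in ks):
        raise ValueError(f"interior knots {knots} must lie strictly inside {boundary}")
    if list(ks) != sorted(set(ks)):
        raise ValueError(f"interior knots must be strictly increasing, got {knots}")

    scalar = np.isscalar(age)
    x = np.atleast_1d(np.asarray(age, dtype=float))
    x = np.clip(x, lo, hi)
    # normalise so the boundary interval is [0, 1]
    t = (x - lo) / (hi - lo)
    xi = np.array([0.0] + [(k - lo) / (hi - lo) for k in ks] + [1.0])
    K = len(xi)

    def d(j: int) -> np.ndarray:
        return (
            np.maximum(t - xi[j], 0.0) ** 3 - np.maximum(t - xi[K - 1], 0.0) ** 3
        ) / (xi[K - 1] - xi[j])

    cols = [t]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    basis = np.column_stack(cols)
    return basis[0] if scalar else basis


def n_basis(knots: tuple[float, ...] = (30.0, 60.0)) -> int:
    """Dimension of the basis: number of interior knots + 1."""
    return len(knots) + 1
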