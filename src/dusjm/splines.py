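"""Natural cubic spline time basis.

The longitudinal submodels describe the evolution of log-transformed duplex
values (PSV, VF) over months since the index procedure with a natural cubic
spline: a cubic spline constrained to be linear beyond its boundary knots.
With a single interior knot placed at the median observation time the basis
(excluding the intercept) has exactly two columns, which keeps the
random-effects dimension workable for a small surveillance cohort.

The basis is built from the truncated-power representation

    d_j(t) = [ (t - k_j)_+^3 - (t - k_K)_+^3 ] / (k_K - k_j)

over the full knot sequence k_1 < ... < k_K (boundary knots included); the
natural-spline columns are  t  and  d_j(t) - d_{K-1}(t)  for the interior
knots j.  All columns, first and second derivatives are analytic, which the
hazard submodel's slope association relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateDesignError(ValueError):
    """Raised when too few distinct times are available to place knots."""


def _pos3(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0.0, x, 0.0) ** 3


def _dpos3(x: np.ndarray) -> np.ndarray:
    return 3.0 * np.where(x > 0.0, x, 0.0) ** 2


def _d2pos3(x: np.ndarray) -> np.ndarray:
    return 6.0 * np.where(x > 0.0, x, 0.0)


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic spline basis over months since procedure.

    ``dimension`` excludes the intercept: one linear column plus one column
    per interior knot.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    dimension: int = field(init=False)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise DegenerateDesignError(
                f"boundary knots must be ordered, got ({lo}, {hi})"
            )
        for k in self.interior_knots:
            if not lo < k < hi:
                raise DegenerateDesignError(
                    f"interior knot {k} not strictly inside boundaries ({lo}, {hi})"
                )
        object.__setattr__(self, "dimension", len(self.interior_knots) + 1)

    @property
    def _all_knots(self) -> np.ndarray:
        return np.array(
            [self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]]
        )

    def _d(self, t: np.ndarray, j: int, fn) -> np.ndarray:
        ks = self._all_knots
        kK = ks[-1]
        return (fn(t - ks[j]) - fn(t - kK)) / (kK - ks[j])

    def _columns(self, t, fn, linear_col) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        K = len(self._all_knots)
        cols = [linear_col(t)]
        for j in range(K - 2):
            cols.append(self._d(t, j, fn) - self._d(t, K - 2, fn))
        return np.column_stack(cols)

    def design(self, t) -> np.ndarray:
        """Evaluate the basis at times ``t`` -> array (n, dimension)."""
        return self._columns(t, _pos3, lambda x: x)

    def deriv(self, t) -> np.ndarray:
        """First derivative of each basis column (per month)."""
        return self._columns(t, _dpos3, np.ones_like)

    def deriv2(self, t) -> np.ndarray:
        """Second derivative of each basis column."""
        return self._columns(t, _d2pos3, np.zeros_like)


def make_ncs_basis(times) -> SplineBasis:
    """Basis with one interior knot at the median observation time.

    Boundary knots at the minimum and maximum of the supplied times.  The
    even-count median is the mean of the two middle order statistics.
    Requires at least three distinct times.
    """
    times = np.asarray(times, dtype=float)
    distinct = np.unique(times)
    if distinct.size < 3:
        raise DegenerateDesignError(
            f"need >= 3 distinct times to place knots, got {distinct.size}"
        )
    knot = float(np.median(times))
    lo, hi = float(distinct[0]), float(distinct[-1])
    if not lo < knot < hi:
        # median may coincide with a boundary in skewed designs; nudge inward
        # to the nearest interior distinct time
        interior = distinct[(distinct > lo) & (distinct < hi)]
        knot = float(interior[np.argmin(np.abs(interior - knot))])
    return SplineBasis(interior_knots=(knot,), boundary_knots=(lo, hi))


def eval_ncs(basis: SplineBasis, t) -> np.ndarray:
    """Row(s) of the natural-spline design at ``t`` (extrapolation allowed)."""
    out = basis.design(t)
    return out[0] if np.isscalar(t) else out
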