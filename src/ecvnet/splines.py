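"""Cubic B-spline bases over the observed range of a variable.

Every parent-child regression in the network model expresses the child's
expression as a sum of smooth functions of its parents' expressions; each
smooth function is a linear combination of ``M`` third-order (cubic) B-spline
basis functions whose knots span the range of the observed parent values.
This module owns the basis construction and evaluation; coefficient fitting
lives in :mod:`ecvnet.local_model`.

Evaluation outside the observed range is clamped to the nearest boundary.
This matters when a model trained on one platform (e.g. microarray) is
evaluated on another cohort (e.g. RNA-seq) whose values can exceed the
training range: clamping returns the boundary contribution instead of an
extrapolated polynomial blow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3  # third-order (cubic) B-splines throughout
DEFAULT_M = 20  # number of basis functions


class DegenerateRangeError(ValueError):
    """All observations identical: no range to place knots on."""


@dataclass(frozen=True)
class SplineBasis:
    """A clamped cubic B-spline basis on ``[support_lo, support_hi]``.

    The knot vector has the first and last knot repeated ``degree + 1``
    times (clamped), with ``M - 4`` interior knots placed uniformly, so the
    basis consists of exactly ``M`` functions forming a partition of unity
    on the support.
    """

    knots: np.ndarray
    support_lo: float
    support_hi: float
    degree: int = DEGREE

    @property
    def M(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def greville(self) -> np.ndarray:
        """Greville abscissae: knot averages at which each basis 'sits'."""
        k = self.degree
        t = self.knots
        return np.array([t[i + 1 : i + k + 1].mean() for i in range(self.M)])

    def __post_init__(self) -> None:
        t = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("knot vector must be nondecreasing")
        object.__setattr__(self, "knots", t)


def build_basis(values, M: int = DEFAULT_M) -> SplineBasis:
    """Build a clamped cubic basis spanning the range of ``values``.

    Parameters
    ----------
    values : array-like
        Observations of one variable; only ``min`` and ``max`` are used.
    M : int
        Number of basis functions (>= 4 for cubics).
    """
    if M < 4:
        raise ValueError(f"cubic basis needs M >= 4 basis functions, got {M}")
    v = np.asarray(values, dtype=float)
    lo, hi = float(np.min(v)), float(np.max(v))
    if not hi > lo:
        raise DegenerateRangeError(
            "all observations identical; cannot place knots on a degenerate range"
        )
    # M cubic basis functions need M + 4 knots: 2*(degree+1) clamped boundary
    # knots plus M - 4 interior ones, i.e. M - 2 uniform breakpoints in total.
    breaks = np.linspace(lo, hi, M - 2)
    knots = np.concatenate([[lo] * DEGREE, breaks, [hi] * DEGREE])
    return SplineBasis(knots=knots, support_lo=lo, support_hi=hi)


def evaluate_basis(basis: SplineBasis, x) -> np.ndarray:
    """Evaluate all ``M`` basis functions at ``x`` (scalar or array).

    ``x`` is clamped to the support first, so out-of-range queries return
    the boundary values. Returns shape ``(M,)`` for scalar input, else
    ``(len(x), M)``.
    """
    scalar = np.ndim(x) == 0
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    xv = np.clip(xv, basis.support_lo, basis.support_hi)
    B = BSpline.design_matrix(xv, basis.knots, basis.degree).toarray()
    return B[0] if scalar else B


def evaluate_spline(basis: SplineBasis, coeffs, x):
    """Evaluate ``sum_l coeffs[l] * b_l(x)`` with boundary clamping."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (basis.M,):
        raise ValueError(
            f"coefficient vector has length {c.shape}, basis has M={basis.M}"
        )
    B = evaluate_basis(basis, x)
    return B @ c
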