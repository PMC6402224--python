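"""p-shift UFIR (unbiased FIR) gain computation.

The degree-``l`` UFIR estimator on a horizon of ``N`` samples with shift
``p`` forms x^_{n|n-p} = sum_{i=p}^{N-1+p} h_i s_{n-i}.  The weights h are
the unique impulse response that reproduces every polynomial of degree <= l
exactly, which makes the estimator unbiased for locally polynomial signals
regardless of the noise distribution.  Negative p gives smoothing with lag
q = -p, p = 0 causal filtering, and p > 0 prediction.  The central choice
p = -(N-1)/2 with odd N recovers the classic Savitzky-Golay smoother.

The weights follow from the normal system of the N x (l+1) Vandermonde
matrix V with rows (1, i, i^2, ..., i^l): h = V (V^T V)^{-1} e1.  Because
the polynomial-reproduction identities (the sum of the weights is 1 and all
moment sums up to order l vanish) must hold to 1e-9 even for N up to ~50
and l up to 4, where the normal system is badly conditioned in floating
point, the (l+1) x (l+1) system is solved in exact rational arithmetic and
converted to float only at the end.  The system is tiny, so this costs
about a millisecond per spec and results are memoised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np

#: Documented practical conditioning bound on the polynomial degree.
MAX_DEGREE = 6


def central_shift(horizon: int) -> int:
    """Shift giving a centred (zero-phase) smoothing window.

    For odd N this is exactly -(N-1)/2; for even N the lag floor((N-1)/2)
    is used so the window stays as central as an integer shift allows.
    """
    return -((horizon - 1) // 2)


@dataclass(frozen=True)
class GainSpec:
    """Degree / horizon / shift triple identifying a UFIR estimator.

    Parameters
    ----------
    degree : int
        Polynomial degree ``l`` reproduced exactly (0 <= l <= 6).
    horizon : int
        Number of samples ``N`` combined per estimate; N >= l + 1.
    shift : int
        Time shift ``p``: p < 0 smoothing (lag q = -p), p = 0 filtering,
        p > 0 prediction.
    """

    degree: int
    horizon: int
    shift: int

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError(f"degree must be non-negative, got {self.degree}")
        if self.degree > MAX_DEGREE:
            raise ValueError(
                f"degree {self.degree} exceeds the practical conditioning "
                f"bound l <= {MAX_DEGREE}"
            )
        if self.horizon < self.degree + 1:
            raise ValueError(
                f"horizon N={self.horizon} must be at least degree+1="
                f"{self.degree + 1}; otherwise the Vandermonde normal system "
                "is singular"
            )

    @property
    def indices(self) -> np.ndarray:
        """Window indices i = p .. N-1+p (ascending)."""
        return np.arange(self.shift, self.shift + self.horizon)


@dataclass
class GainVector:
    """UFIR impulse response for one :class:`GainSpec`.

    ``h[k]`` is the weight on s_{n-i} with i = shift + k, i.e. the weights
    are stored ascending in the window index i.  ``poly_coeffs`` are the
    a_j coefficients such that h_i = sum_j a_j i^j.
    """

    spec: GainSpec
    h: np.ndarray
    poly_coeffs: np.ndarray = field(repr=False, default=None)

    @property
    def npg(self) -> float:
        """Noise power gain: sum of squared weights.

        White noise of variance sigma^2 at the input leaves the estimator
        with variance npg * sigma^2.
        """
        return float(np.dot(self.h, self.h))


def _solve_rational(D: list[list[Fraction]], rhs: list[Fraction]) -> list[Fraction]:
    """Gauss-Jordan solve of a small rational system."""
    n = len(D)
    A = [row[:] + [rhs[k]] for k, row in enumerate(D)]
    for col in range(n):
        piv = next((r for r in range(col, n) if A[r][col] != 0), None)
        if piv is None:
            raise np.linalg.LinAlgError("singular normal system")
        A[col], A[piv] = A[piv], A[col]
        pv = A[col][col]
        A[col] = [x / pv for x in A[col]]
        for r in range(n):
            if r != col and A[r][col] != 0:
                f = A[r][col]
                A[r] = [x - f * y for x, y in zip(A[r], A[col])]
    return [A[r][n] for r in range(n)]


@lru_cache(maxsize=4096)
def _gains_cached(degree: int, horizon: int, shift: int):
    idx = range(shift, shift + horizon)
    m = degree + 1
    # V^T V over integer window indices, exact
    powers = [[Fraction(i) ** j for j in range(m)] for i in idx]
    D = [
        [sum(powers[r][a] * powers[r][b] for r in range(horizon)) for b in range(m)]
        for a in range(m)
    ]
    e1 = [Fraction(1 if k == 0 else 0) for k in range(m)]
    a = _solve_rational(D, e1)
    h = [sum(a[j] * powers[r][j] for j in range(m)) for r in range(horizon)]
    return (
        np.array([float(x) for x in h]),
        np.array([float(x) for x in a]),
    )


def compute_gains(spec: GainSpec) -> GainVector:
    """Compute the UFIR impulse response for ``spec``.

    Returns
    -------
    GainVector
        Weights ``h`` ascending in the window index i = p .. N-1+p, with
        sum(h) = 1 and vanishing moment sums up to order ``spec.degree``.

    Raises
    ------
    ValueError
        If the spec violates N >= l+1 or l <= 6 (raised at spec creation).
    """
    h, a = _gains_cached(spec.degree, spec.horizon, spec.shift)
    return GainVector(spec=spec, h=h.copy(), poly_coeffs=a.copy())


def export_gains_csv(specs, path) -> None:
    """Write gain weight tables for inspection, one row per (spec, i, h_i)."""
    import pandas as pd

    rows = []
    for spec in specs:
        gv = compute_gains(spec)
        for i, w in zip(spec.indices, gv.h):
            rows.append(
                {
                    "degree": spec.degree,
                    "horizon": spec.horizon,
                    "shift": spec.shift,
                    "i": int(i),
                    "h": w,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
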