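"""Matrix inversion as a polynomial in the matrix itself.

By the Cayley–Hamilton theorem an invertible n x n matrix satisfies its own
characteristic polynomial

    p(A) = A^n + c_{n-1} A^{n-1} + ... + c_1 A + (-1)^n det(A) I = 0,

so its inverse is the degree-(n-1) matrix polynomial

    A^{-1} = (-1)^{n-1} / det(A) * (A^{n-1} + c_{n-1} A^{n-2} + ... + c_1 I).

The coefficients c_i are signed elementary symmetric functions of the
eigenvalues; via the Newton identities they are obtained from the power sums
s_k = tr(A^k) through complete Bell polynomials of the signed,
factorial-scaled power sums:

    e_k = B_k(s_1, -1! s_2, 2! s_3, ..., (-1)^{k-1} (k-1)! s_k) / k!,
    c_{n-k} = (-1)^k e_k,     det(A) = e_n.

Truncating the series after its p+1 highest-order terms (A^{n-1} down to
A^{n-p-1}, prefactor retained) yields the cheap approximate inverse that the
trainable polynomial network generalises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CharPoly",
    "SingularMatrixError",
    "power_sums",
    "bell_coefficients",
    "char_poly",
    "poly_inverse_exact",
    "poly_inverse_truncated",
]

# |det| below DET_FLOOR_FACTOR * max(|s_1|/n, 1)^n counts as singular; the
# scale term keeps the floor meaningful for matrices far from unit scale.
DET_FLOOR_FACTOR = 1e-12


class SingularMatrixError(ValueError):
    """Raised when the computed determinant is below the singularity floor."""

    def __init__(self, determinant: float, floor: float):
        self.determinant = determinant
        self.floor = floor
        super().__init__(
            f"matrix is singular or near-singular: |det| = {abs(determinant):.3e} "
            f"<= floor {floor:.3e}"
        )


@dataclass(frozen=True)
class CharPoly:
    """Characteristic polynomial data of an n x n matrix.

    ``coefficients`` holds c_1 ... c_{n-1} (empty for n = 1); the polynomial
    is ``lambda^n + c_{n-1} lambda^{n-1} + ... + c_1 lambda + (-1)^n det``.
    ``power_sums`` holds s_1 ... s_n with s_k = tr(A^k).
    """

    dimension: int
    coefficients: np.ndarray
    determinant: float
    power_sums: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        s = np.asarray(self.power_sums, dtype=float)
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if len(c) != self.dimension - 1:
            raise ValueError(
                f"expected {self.dimension - 1} coefficients, got {len(c)}"
            )
        if len(s) != self.dimension:
            raise ValueError(f"expected {self.dimension} power sums, got {len(s)}")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(s)) and np.isfinite(self.determinant)):
            raise ValueError("characteristic polynomial data must be finite")
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "power_sums", s)


def _as_square(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    return a


def power_sums(a: np.ndarray, n: int | None = None) -> np.ndarray:
    """Power sums s_k = tr(A^k) = sum_i lambda_i^k for k = 1 ... n."""
    a = _as_square(a)
    dim = a.shape[0]
    if n is None:
        n = dim
    elif n != dim:
        raise ValueError(f"n = {n} does not match matrix dimension {dim}")
    out = np.empty(n)
    power = a
    for k in range(n):
        out[k] = np.trace(power)
        if k < n - 1:
            power = power @ a
    return out


def _elementary_symmetric(s: np.ndarray) -> np.ndarray:
    """e_1 ... e_n from power sums via the complete Bell recurrence.

    With x_i = (-1)^{i-1} (i-1)! s_i the complete Bell polynomials satisfy
    B_k = sum_{i=1}^{k} C(k-1, i-1) x_i B_{k-i}, and e_k = B_k / k!.
    """
    n = len(s)
    x = [(-1.0) ** (i - 1) * math.factorial(i - 1) * s[i - 1] for i in range(1, n + 1)]
    bell = [1.0]
    for k in range(1, n + 1):
        bell.append(
            sum(math.comb(k - 1, i - 1) * x[i - 1] * bell[k - i] for i in range(1, k + 1))
        )
    return np.array([bell[k] / math.factorial(k) for k in range(1, n + 1)])


def bell_coefficients(power_sums_values) -> CharPoly:
    """Characteristic-polynomial coefficients from power sums s_1 ... s_n."""
    s = np.asarray(power_sums_values, dtype=float)
    if s.ndim != 1 or len(s) == 0:
        raise ValueError("power sums must be a nonempty 1-D sequence")
    n = len(s)
    e = _elementary_symmetric(s)
    # c_{n-k} = (-1)^k e_k for k = 1 ... n-1; determinant is e_n.
    coeffs = np.array([(-1.0) ** (n - i) * e[n - i - 1] for i in range(1, n)])
    return CharPoly(
        dimension=n,
        coefficients=coeffs,
        determinant=float(e[n - 1]),
        power_sums=s,
    )


def char_poly(a: np.ndarray) -> CharPoly:
    """Characteristic polynomial of ``a`` via power sums and Bell polynomials."""
    return bell_coefficients(power_sums(a))


def _det_floor(cp: CharPoly) -> float:
    scale = max(abs(cp.power_sums[0]) / cp.dimension, 1.0)
    return DET_FLOOR_FACTOR * scale**cp.dimension


def _series_terms(a: np.ndarray, cp: CharPoly):
    """Yield (coefficient, A^power) pairs for powers n-1 down to 0.

    Term k (k = 0 ... n-1) is c_{n-k} * A^{n-1-k} with c_n taken as 1.
    """
    n = cp.dimension
    full = np.concatenate([cp.coefficients, [1.0]])  # c_1 ... c_{n-1}, c_n = 1
    powers = [np.eye(n)]
    for _ in range(n - 1):
        powers.append(powers[-1] @ a)
    for k in range(n):
        yield full[n - 1 - k], powers[n - 1 - k]


def poly_inverse_truncated(a: np.ndarray, p: int) -> np.ndarray:
    """Truncated characteristic-polynomial inverse keeping p + 1 terms.

    Retains the highest-order terms A^{n-1} ... A^{n-p-1} of the exact series
    together with the (-1)^{n-1}/det prefactor.  ``p = n - 1`` reproduces
    :func:`poly_inverse_exact` exactly.
    """
    a = _as_square(a)
    n = a.shape[0]
    if not 0 <= p <= n - 1:
        raise ValueError(f"truncation order p = {p} outside [0, {n - 1}]")
    cp = char_poly(a)
    floor = _det_floor(cp)
    if abs(cp.determinant) <= floor:
        raise SingularMatrixError(cp.determinant, floor)
    acc = np.zeros_like(a)
    for k, (coeff, power) in enumerate(_series_terms(a, cp)):
        if k > p:
            break
        acc += coeff * power
    return (-1.0) ** (n - 1) / cp.determinant * acc


def poly_inverse_exact(a: np.ndarray) -> np.ndarray:
    """Exact inverse via the full Cayley–Hamilton series."""
    a = _as_square(a)
    return poly_inverse_truncated(a, a.shape[0] - 1)
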