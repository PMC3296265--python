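"""Shared subspace linear algebra: Hankel matrices, shift pairs, rank
truncation, LS/TLS shift solvers, pole extraction and un-decimation.

All index conventions are 0-based; the Hankel observation matrix has entry
``(i, j) = s(i + j)``.  A decimation factor ``D`` relates matrices offset by
``D`` samples, so extracted eigenvalues are D-th powers of the signal poles
("decimated poles"), multiplying angular separations by D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .model import TimeSeries

__all__ = [
    "HankelSpec",
    "ShiftPair",
    "PoleSet",
    "AliasingWarning",
    "NongenericTLSError",
    "default_dims",
    "build_hankel",
    "shift_pair",
    "rank_truncate",
    "solve_shift_ls",
    "solve_shift_tls",
    "dominant_eigenvalues",
    "undecimate_pole",
    "pole_from_params",
    "fit_linear_params",
]


class AliasingWarning(UserWarning):
    """A decimated pole sits near the wrapped angle boundary; f may be aliased."""


class NongenericTLSError(np.linalg.LinAlgError):
    """The TLS problem is nongeneric: the bottom-right right-singular block is singular."""


@dataclass(frozen=True)
class HankelSpec:
    """Dimensions of the L x M Hankel matrix and the shift offset D, with L+M-1=N."""

    L: int
    M: int
    D: int
    N: int

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("decimation factor D must be >= 1")
        if self.L + self.M - 1 != self.N:
            raise ValueError("HankelSpec requires L + M - 1 = N")
        if self.L - self.D < 1:
            raise ValueError("need L - D >= 1 for a nonempty shift pair")
        if self.L - self.D > self.M:
            raise ValueError("HankelSpec requires L - D <= M")

    @property
    def rows(self) -> int:
        """Row count of the shifted matrices, L - D."""
        return self.L - self.D


@dataclass(frozen=True)
class ShiftPair:
    """The (L-D) x M pair: up = bottom-D-rows-deleted, down = top-D-rows-deleted."""

    up: np.ndarray
    down: np.ndarray
    spec: HankelSpec


@dataclass(frozen=True)
class PoleSet:
    """p extracted (decimated) poles plus the factor D and sampling frequency."""

    poles: np.ndarray
    D: int
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.poles, dtype=complex)
        arr.setflags(write=False)
        object.__setattr__(self, "poles", arr)
        if not np.all(np.isfinite(arr)):
            raise ValueError("poles must be finite")

    @property
    def p(self) -> int:
        return self.poles.size


def default_dims(N: int, D: int, p: int | None = None) -> HankelSpec:
    """Near-square default sizing: M = floor(N/2), L = N + 1 - M.

    The shift-pair row count L - D shrinks only by one row per unit of D, so
    the usable model order is essentially unconstrained by decimation.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    L = (N + 2) // 2  # ceil((N+1)/2): 65 x 64 at N=128, square at odd N
    M = N + 1 - L
    spec = HankelSpec(L=L, M=M, D=D, N=N)
    if p is not None and not (0 < p < spec.rows):
        raise ValueError(f"order p={p} infeasible: need 0 < p < L - D = {spec.rows}")
    return spec


def build_hankel(ts: TimeSeries | np.ndarray, spec: HankelSpec) -> np.ndarray:
    """L x M Hankel observation matrix with entry (i, j) = s(i + j)."""
    s = ts.samples if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=complex)
    if s.size != spec.N:
        raise ValueError(f"series length {s.size} does not match spec N={spec.N}")
    return sla.hankel(s[: spec.L], s[spec.L - 1 :])


def shift_pair(S_H: np.ndarray, D: int, spec: HankelSpec | None = None) -> ShiftPair:
    """Delete the bottom (up) and top (down) D rows of a Hankel matrix."""
    L, M = S_H.shape
    if not (1 <= D < L):
        raise ValueError(f"D={D} must satisfy 1 <= D < L={L}")
    if spec is None:
        spec = HankelSpec(L=L, M=M, D=D, N=L + M - 1)
    return ShiftPair(up=S_H[:-D], down=S_H[D:], spec=spec)


def rank_truncate(A: np.ndarray, p: int, return_svd: bool = False):
    """Best rank-p approximation of A (Eckart-Young) via SVD.

    With ``return_svd=True`` also returns the truncated factors (U_p, s_p, Vh_p)
    so a later pseudoinverse can reuse the decomposition.
    """
    if not (1 <= p <= min(A.shape)):
        raise ValueError(f"order p={p} must lie in [1, min{A.shape}]")
    U, s, Vh = sla.svd(A, full_matrices=False)
    Ap = (U[:, :p] * s[:p]) @ Vh[:p]
    if return_svd:
        return Ap, (U[:, :p], s[:p], Vh[:p])
    return Ap


def solve_shift_ls(
    A: np.ndarray,
    B: np.ndarray,
    side: str = "left",
    svd: tuple | None = None,
) -> np.ndarray:
    """Minimum-norm least-squares solution of the shift equation.

    side='left' solves X A = B as X = B pinv(A); side='right' solves A Q = B
    as Q = pinv(A) B.  When ``svd=(U_p, s_p, Vh_p)`` is supplied (rank-p
    factors of A from :func:`rank_truncate`), the pseudoinverse reuses it, so
    the result has rank <= p.
    """
    if svd is not None:
        Up, sp, Vhp = svd
        pinvA = (Vhp.conj().T * (1.0 / sp)) @ Up.conj().T
    else:
        pinvA = np.linalg.pinv(A)
    if side == "left":
        if A.shape[1] != B.shape[1]:
            raise ValueError("X A = B needs matching column counts")
        return B @ pinvA
    elif side == "right":
        if A.shape[0] != B.shape[0]:
            raise ValueError("A Q = B needs matching row counts")
        return pinvA @ B
    raise ValueError("side must be 'left' or 'right'")


def solve_shift_tls(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Classical SVD-based total-least-squares solution of A Q ~= B.

    The right singular vectors of the stacked matrix [A | B] are partitioned
    as [[V11, V12], [V21, V22]]; the TLS solution is Q = -V12 V22^{-1}.
    Raises :class:`NongenericTLSError` when V22 is singular (nongeneric TLS).
    """
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must have the same row count")
    k, m = A.shape[1], B.shape[1]
    _, _, Vh = sla.svd(np.hstack([A, B]), full_matrices=True)
    V = Vh.conj().T
    V12 = V[:k, k : k + m]
    V22 = V[k:, k : k + m]
    # Guard against the nongeneric case before inverting.
    if min(V22.shape) == 0 or np.linalg.cond(V22) > 1e12:
        raise NongenericTLSError(
            "nongeneric TLS problem: bottom-right right-singular block is singular"
        )
    return -V12 @ np.linalg.inv(V22)


def dominant_eigenvalues(X: np.ndarray, p: int, D: int = 1, fs: float = 1.0) -> PoleSet:
    """The p largest-magnitude eigenvalues of X, as a PoleSet.

    Ordered by descending magnitude, ties broken by ascending phase angle, so
    extraction is deterministic.
    """
    if not (1 <= p <= X.shape[0]):
        raise ValueError(f"order p={p} must lie in [1, {X.shape[0]}]")
    w = sla.eigvals(X)
    order = np.lexsort((np.angle(w), -np.abs(w)))
    return PoleSet(poles=w[order][:p], D=D, fs=fs)


def undecimate_pole(lam: complex, D: int, fs: float) -> tuple[float, float]:
    """Convert a decimated pole z^D back to (f in Hz, d in rad/s).

    f = angle(lam) * fs / (2 pi D) with angle in (-pi, pi]; d = -ln|lam| * fs / D.
    Assumes the alias-free regime D*|f|/fs < 1/2; wrapped angles are returned
    as-is (see :class:`AliasingWarning` at the estimator level).
    """
    lam = complex(lam)
    if lam == 0:
        raise ValueError("cannot un-decimate a zero pole")
    f = np.angle(lam) * fs / (2 * np.pi * D)
    d = -np.log(abs(lam)) * fs / D
    return float(f), float(d)


def pole_from_params(f: float, d: float, fs: float, D: int = 1) -> complex:
    """The (optionally decimated) pole exp(((-d + j 2 pi f)/fs) * D)."""
    return complex(np.exp((-d + 2j * np.pi * f) * D / fs))


def fit_linear_params(ts: TimeSeries | np.ndarray, poles: np.ndarray) -> np.ndarray:
    """Least-squares complex linear parameters g of the Vandermonde system.

    Solves V g = s with V[n, i] = z_i^n over all N samples; amplitudes are
    |g_i| and phases angle(g_i).  Duplicate poles make V singular and raise.
    """
    s = ts.samples if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=complex)
    z = np.asarray(poles, dtype=complex)
    if z.size > s.size:
        raise ValueError("more poles than samples")
    if np.unique(np.round(z, 12)).size != z.size:
        raise np.linalg.LinAlgError("duplicate poles: Vandermonde system is singular")
    n = np.arange(s.size)
    V = z[None, :] ** n[:, None]
    g, *_ = sla.lstsq(V, s, lapack_driver="gelsd")
    return g
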