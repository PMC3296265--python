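"""Cramér–Rao lower bounds for the damped-cisoid model and the
failure-interval half-width construction.

For a deterministic complex signal observed in circular complex white
Gaussian noise whose real and imaginary components each have standard
deviation ``sigma_v``, the Fisher information over the real parameter vector
theta is::

    FIM[k, l] = (1/sigma_v^2) * sum_n Re( conj(ds(n)/dtheta_k) * ds(n)/dtheta_l )

with analytic partial derivatives of the model signal.  Parameters are
ordered (f_1, d_1, b_1, psi_1, ..., f_p, d_p, b_p, psi_p); the phase is
differentiated in radians internally and converted back to degrees when
bounds are reported.

The failure intervals of the Monte-Carlo protocol are symmetric frequency
intervals around the true peaks, sized so that the two intervals of a chosen
anchor pair exactly touch.  Because the CRLB standard deviations are linear
in sigma_v, the touching condition fixes only the *split* of the anchor
separation, proportional to the two frequency bounds; any common scale (the
reference sigma, or a k-sigma interval convention) cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SinusoidModel

__all__ = [
    "FisherInfo",
    "HalfWidths",
    "signal_jacobian",
    "fisher_information",
    "crlb_std",
    "touching_half_widths",
]

# Unit conversion applied to the sqrt-CRLB diagonal, per peak:
# (f Hz, d rad/s, b linear, psi radians -> degrees).
_UNIT_OUT = np.array([1.0, 1.0, 1.0, 180.0 / np.pi])


@dataclass(frozen=True)
class FisherInfo:
    """4p x 4p real symmetric Fisher information (phase block in radians)."""

    matrix: np.ndarray
    sigma_v: float
    N: int
    fs: float


@dataclass(frozen=True)
class HalfWidths:
    """Per-peak failure-interval half-widths in Hz, with the anchor pair.

    ``sigma_star`` is the noise standard deviation (in units of the reference
    sigma used for the CRLBs) at which the two one-sigma anchor intervals
    touch.
    """

    half_widths: tuple[float, ...]
    anchor_pair: tuple[int, int]
    sigma_star: float


def signal_jacobian(model: SinusoidModel, N: int) -> np.ndarray:
    """Complex N x 4p Jacobian of the model signal w.r.t. the real parameters.

    Phase derivatives are taken in radians.
    """
    n = np.arange(N)
    cols = []
    for pk in model.peaks:
        s = (
            pk.b
            * np.exp(1j * np.deg2rad(pk.psi))
            * np.exp((-pk.d + 2j * np.pi * pk.f) * n / model.fs)
        )
        cols.append(2j * np.pi * n / model.fs * s)  # d/df
        cols.append(-n / model.fs * s)  # d/dd
        cols.append(s / pk.b if pk.b != 0 else np.exp(
            1j * np.deg2rad(pk.psi)
            + (-pk.d + 2j * np.pi * pk.f) * n / model.fs))  # d/db
        cols.append(1j * s)  # d/dpsi (radians)
    return np.array(cols).T


def fisher_information(model: SinusoidModel, N: int, sigma_v: float) -> FisherInfo:
    """Fisher information of all 4p real parameters at noise level sigma_v."""
    if sigma_v <= 0:
        raise ValueError("sigma_v must be positive")
    J = signal_jacobian(model, N)
    F = np.real(J.conj().T @ J) / sigma_v**2
    F = 0.5 * (F + F.T)  # enforce exact symmetry
    return FisherInfo(matrix=F, sigma_v=sigma_v, N=N, fs=model.fs)


def crlb_std(model: SinusoidModel, N: int, sigma_v: float) -> np.ndarray:
    """Sqrt-CRLB of each parameter, in caller units (Hz, rad/s, linear, degrees).

    Returns a length-4p vector: sqrt of the diagonal of the inverse Fisher
    information, ordered (f_1, d_1, b_1, psi_1, ...).
    """
    info = fisher_information(model, N, sigma_v)
    if np.linalg.cond(info.matrix) > 1e14:
        raise np.linalg.LinAlgError(
            "singular Fisher information (coincident or degenerate peaks)"
        )
    cov = np.linalg.inv(info.matrix)
    diag = np.diag(cov)
    if np.any(diag < -1e-12 * np.abs(diag).max()):
        raise np.linalg.LinAlgError(
            "Fisher information is numerically singular (negative CRLB variance)"
        )
    std = np.sqrt(np.maximum(diag, 0.0))
    return std * np.tile(_UNIT_OUT, model.p)


def touching_half_widths(
    model: SinusoidModel, N: int, pair: tuple[int, int], sigma_ref: float = 1.0
) -> HalfWidths:
    """Failure-interval half-widths from the CRLB touching construction.

    The anchor pair's frequency separation is split in proportion to the two
    peaks' frequency sqrt-CRLBs, which is the unique assignment making the
    symmetric intervals touch; all other peaks receive the larger anchor
    half-width.  ``pair`` uses 0-based peak indices.
    """
    i, j = pair
    p = model.p
    if not (0 <= i < p and 0 <= j < p and i != j):
        raise ValueError("anchor pair must be two distinct valid peak indices")
    fi, fj = model.peaks[i].f, model.peaks[j].f
    delta_f = abs(fi - fj)
    if delta_f == 0:
        raise ValueError("anchor peaks must have distinct frequencies")
    c = crlb_std(model, N, sigma_ref)
    ci, cj = c[4 * i], c[4 * j]
    hw_i = delta_f * ci / (ci + cj)
    hw_j = delta_f * cj / (ci + cj)
    hw_max = max(hw_i, hw_j)
    hw = [hw_max] * p
    hw[i], hw[j] = hw_i, hw_j
    return HalfWidths(
        half_widths=tuple(hw),
        anchor_pair=(i, j),
        sigma_star=delta_f / (ci + cj) * sigma_ref,
    )
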