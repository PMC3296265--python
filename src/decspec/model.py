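"""Damped complex-sinusoid signal model, synthesis, noise, and built-in presets.

The time-domain signal (an FID-like series) is a sum of ``p`` exponentially
damped cisoids sampled uniformly at ``fs``::

    s(n) = sum_i  b_i * exp(j*psi_i) * exp((-d_i + j*2*pi*f_i) * n / fs)

with frequency ``f_i`` in Hz, damping ``d_i`` in rad/s, linear amplitude
``b_i`` and phase ``psi_i`` (stored in degrees, converted at synthesis).
Measured signals add circular complex white Gaussian noise whose real and
imaginary components are each i.i.d. N(0, sigma_v^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Peak",
    "SinusoidModel",
    "TimeSeries",
    "Preset",
    "synthesize",
    "add_noise",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class Peak:
    """One damped cisoid: frequency (Hz), damping (rad/s), amplitude, phase (deg)."""

    f: float
    d: float
    b: float
    psi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.f) and np.isfinite(self.d)):
            raise ValueError("peak frequency and damping must be finite")
        if not (np.isfinite(self.b) and self.b >= 0):
            raise ValueError("peak amplitude must be finite and >= 0")


@dataclass(frozen=True)
class SinusoidModel:
    """Ground-truth parameter set: ordered peaks plus sampling frequency (Hz)."""

    peaks: tuple[Peak, ...]
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.peaks) < 1:
            raise ValueError("model needs at least one peak")
        for pk in self.peaks:
            if not (-self.fs / 2 < pk.f <= self.fs / 2):
                raise ValueError(
                    f"frequency {pk.f} Hz outside (-fs/2, fs/2] for fs={self.fs}"
                )

    @property
    def p(self) -> int:
        """Model order: number of damped cisoids."""
        return len(self.peaks)

    def frequencies(self) -> np.ndarray:
        return np.array([pk.f for pk in self.peaks])

    def dampings(self) -> np.ndarray:
        return np.array([pk.d for pk in self.peaks])

    def amplitudes(self) -> np.ndarray:
        return np.array([pk.b for pk in self.peaks])

    def phases(self) -> np.ndarray:
        return np.array([pk.psi for pk in self.peaks])


@dataclass(frozen=True)
class TimeSeries:
    """N uniformly sampled complex values with sampling frequency fs (Hz).

    ``sigma_v`` records the per-component noise standard deviation used to
    generate the series (0 for noise-free); ``seed`` the generator seed, if any.
    """

    samples: np.ndarray
    fs: float
    sigma_v: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=complex)
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")

    @property
    def N(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class Preset:
    """A named reference signal: model, default length, failure half-widths (Hz)."""

    name: str
    model: SinusoidModel
    default_N: int
    half_widths: tuple[float, ...]


def synthesize(model: SinusoidModel, N: int) -> TimeSeries:
    """Evaluate the noise-free model at samples n = 0..N-1.

    Parameters
    ----------
    model : SinusoidModel
    N : int
        Number of samples, >= 1.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    n = np.arange(N)
    s = np.zeros(N, dtype=complex)
    for pk in model.peaks:
        g = pk.b * np.exp(1j * np.deg2rad(pk.psi))
        s += g * np.exp((-pk.d + 2j * np.pi * pk.f) * n / model.fs)
    return TimeSeries(samples=s, fs=model.fs, sigma_v=0.0)


def add_noise(ts: TimeSeries, sigma_v: float, seed=None) -> TimeSeries:
    """Add circular complex white Gaussian noise.

    Real and imaginary perturbations are independent N(0, sigma_v^2) per sample.
    Identical (ts, sigma_v, seed) triples yield bit-identical output.
    """
    if sigma_v < 0:
        raise ValueError("sigma_v must be >= 0")
    if sigma_v == 0:
        return ts
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_v, ts.N) + 1j * rng.normal(0.0, sigma_v, ts.N)
    scalar_seed = seed if isinstance(seed, (int, np.integer)) else None
    return TimeSeries(
        samples=ts.samples + noise, fs=ts.fs, sigma_v=sigma_v, seed=scalar_seed
    )


def _mk(name, fs, rows, default_N, half_widths):
    peaks = tuple(Peak(*r) for r in rows)
    return Preset(
        name=name,
        model=SinusoidModel(peaks=peaks, fs=fs),
        default_N=default_N,
        half_widths=tuple(half_widths),
    )


# Built-in reference signals.  two_peak is the classic 0.2/0.22 Hz pair used
# throughout the subspace-estimation literature; the other two emulate 31P NMR
# spectra (perfused rat liver style).  Half-widths are the published
# failure-interval half-widths in Hz.
_PRESETS = {
    "two_peak": _mk(
        "two_peak",
        1.0,
        [(0.2, 0.01, 1.0, 0.0), (0.22, 0.02, 1.0, 0.0)],
        128,
        (0.0094, 0.0106),
    ),
    "five_peak_31p": _mk(
        "five_peak_31p",
        10_000.0,
        [
            (-1379.0, 208.0, 6.1, 15.0),
            (-685.0, 256.0, 9.9, 15.0),
            (-271.0, 197.0, 6.0, 15.0),
            (353.0, 117.0, 2.8, 15.0),
            (478.0, 808.0, 17.0, 15.0),
        ],
        128,
        (82.0, 82.0, 82.0, 43.0, 82.0),
    ),
    "eleven_peak_31p": _mk(
        "eleven_peak_31p",
        3_000.0,
        [
            (-86.0, 50.0, 75.0, 135.0),
            (-70.0, 50.0, 150.0, 135.0),
            (-54.0, 50.0, 75.0, 135.0),
            (152.0, 50.0, 150.0, 135.0),
            (168.0, 50.0, 150.0, 135.0),
            (292.0, 50.0, 150.0, 135.0),
            (308.0, 50.0, 150.0, 135.0),
            (360.0, 25.0, 150.0, 135.0),
            (440.0, 285.7, 1400.0, 135.0),
            (490.0, 25.0, 60.0, 135.0),
            (530.0, 200.0, 500.0, 135.0),
        ],
        128,
        (8.6, 7.3, 8.6, 3.2, 3.2, 3.4, 3.6, 7.4, 5.5, 2.3, 7.7),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> Preset:
    """Return a built-in preset by name (two_peak, five_peak_31p, eleven_peak_31p)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        ) from None
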