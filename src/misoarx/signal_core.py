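"""Shared domain types and signal arithmetic.

The measurement model throughout the package is

    y(t) = s(t) + e(t),

a single-trial evoked potential s buried in ongoing EEG e.  All stages
exchange :class:`SampledSignal` instances — uniformly sampled real
waveforms with an explicit sampling rate — and the two polynomial types
that parameterize the ARX machinery:

* :class:`ARPolynomial` with the fixed sign convention
  ``A(z^-1) = 1 - sum_i a_i z^-i``, and
* :class:`MAWithDelay`, a lag-absorbed moving-average numerator
  ``B(z^-1) = z^-d * sum_j b_j z^-j``.

Delays are signed integer sample counts: a positive delay retards the
input, a negative delay advances it (the component occurs *earlier* in
the trial than in the template).  Out-of-range input samples are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sps

from .exceptions import DimensionError

__all__ = [
    "SampledSignal",
    "Epoch",
    "ARPolynomial",
    "MAWithDelay",
    "add_signals",
    "measure_snr",
    "filter_arma",
    "shift_samples",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples
        1-D array of finite real values, length >= 1.
    rate
        Sampling rate in samples per second (or per model time unit).
    t0
        Time of the first sample, seconds (default 0).
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not (self.rate > 0):
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span of the signal in time units (n / rate)."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Time of each sample: t0 + index / rate."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    def with_samples(self, samples: np.ndarray) -> "SampledSignal":
        """A copy carrying new samples but the same rate and t0."""
        return SampledSignal(np.asarray(samples, dtype=float), self.rate, self.t0)


@dataclass(frozen=True)
class Epoch:
    """One stimulus-locked trial.

    ``stimulus_onset`` is in seconds relative to ``signal.t0`` and must
    fall within the signal span.
    """

    signal: SampledSignal
    trial_index: int
    stimulus_onset: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.stimulus_onset <= self.signal.duration):
            raise ValueError("stimulus_onset outside the signal span")


@dataclass(frozen=True)
class ARPolynomial:
    """Autoregressive polynomial ``A(z^-1) = 1 - sum_i a_i z^-i``.

    ``coeffs`` holds a_1 .. a_n.  The order-0 polynomial (no
    coefficients) is the identity A = 1.
    """

    coeffs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if arr.ndim != 1 or not np.all(np.isfinite(arr)):
            raise ValueError("AR coefficients must be a finite 1-D sequence")
        object.__setattr__(self, "coeffs", arr)

    @property
    def order(self) -> int:
        return self.coeffs.size

    def as_lfilter_a(self) -> np.ndarray:
        """Denominator in scipy ``lfilter`` convention: [1, -a1, ..., -an]."""
        return np.concatenate(([1.0], -self.coeffs))

    def roots(self) -> np.ndarray:
        """Characteristic roots (in z); stable iff all inside unit circle."""
        if self.order == 0:
            return np.empty(0, dtype=complex)
        return np.roots(self.as_lfilter_a())

    def is_stable(self) -> bool:
        r = self.roots()
        return bool(r.size == 0 or np.all(np.abs(r) < 1.0))

    def apply_fir(self, x: np.ndarray) -> np.ndarray:
        """Apply A(z^-1) as an FIR filter (whitening direction)."""
        return _sps.lfilter(self.as_lfilter_a(), [1.0], np.asarray(x, dtype=float))


@dataclass(frozen=True)
class MAWithDelay:
    """Lag-absorbed moving-average numerator with an integer delay.

    Represents ``B(z^-1) u(t) = sum_{j=0}^{m-1} b_j u(t - j - d)``.  The
    delay ``d`` absorbs both the structural input delay and the
    component's latency shift relative to the template, so it is signed:
    negative values advance the input.  The gain k of the original
    component is absorbed into the b_j and is not separately
    recoverable.
    """

    coeffs: np.ndarray
    delay: int = 0

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if arr.ndim != 1 or arr.size < 1 or not np.all(np.isfinite(arr)):
            raise ValueError("MA coefficients must be a non-empty finite 1-D sequence")
        object.__setattr__(self, "coeffs", arr)
        object.__setattr__(self, "delay", int(self.delay))

    @property
    def order(self) -> int:
        return self.coeffs.size


def shift_samples(x: np.ndarray, shift: int) -> np.ndarray:
    """Translate an array by ``shift`` samples, zero-padding the ends.

    Positive shifts move content toward later indices.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if shift == 0:
        out[:] = x
    elif shift > 0:
        if shift < x.size:
            out[shift:] = x[:-shift]
    else:
        if -shift < x.size:
            out[:shift] = x[-shift:]
    return out


def add_signals(a: SampledSignal, b: SampledSignal) -> SampledSignal:
    """Elementwise sum y = s + e of two equally sampled signals."""
    if a.n != b.n:
        raise DimensionError(f"length mismatch: {a.n} vs {b.n}")
    if a.rate != b.rate:
        raise DimensionError(f"rate mismatch: {a.rate} vs {b.rate}")
    return a.with_samples(a.samples + b.samples)


def measure_snr(signal: SampledSignal, noise: SampledSignal) -> float:
    """Signal-to-noise ratio in dB: 10 log10(mean(s^2) / mean(e^2)).

    Mean power is taken over the whole epoch.  Zero noise power yields
    +inf, zero signal power -inf.
    """
    if signal.n != noise.n:
        raise DimensionError(f"length mismatch: {signal.n} vs {noise.n}")
    ps = float(np.mean(signal.samples**2))
    pe = float(np.mean(noise.samples**2))
    if pe == 0.0:
        return float("inf")
    if ps == 0.0:
        return float("-inf")
    return 10.0 * np.log10(ps / pe)


def filter_arma(
    input: SampledSignal, num: MAWithDelay, den: ARPolynomial
) -> SampledSignal:
    """Filter a signal through ``B(z^-1)/A(z^-1)`` with zero initial state.

    The output obeys the recursion

        o(t) = sum_i a_i o(t-i) + sum_j b_j u(t - j - d),

    with u taken as zero outside its support, and has the same length as
    the input.  A negative delay advances u (zero-padded at the end)
    before the causal part of the filter is applied.
    """
    x = input.samples
    if num.delay >= 0:
        b = np.concatenate((np.zeros(num.delay), num.coeffs))
    else:
        x = shift_samples(x, num.delay)
        b = num.coeffs
    y = _sps.lfilter(b, den.as_lfilter_a(), x)
    return input.with_samples(y)
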