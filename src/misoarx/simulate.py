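"""Synthetic benchmark data: sinc-sum reference EP, AR(4) EEG, SNR mixtures.

The simulated evoked potential is the superposition of three sinc-shaped
components with amplitudes 0.25, 0.5 and 1,

    u(t) = 0.25 sinc(0.13 pi (4t - 8))
         + 0.50 sinc(0.13 pi (4t - 16))
         +      sinc(0.13 pi (4t - 24 + l)),

with the normalized sinc(x) = sin(pi x)/(pi x), whose main lobe
(half-width 0.61 time units) is narrow enough that the three waves stay
visually and topographically distinct at their 2-unit spacing.  The
lobes peak at t = 2, 4 and (24 - l)/4 time units; the parameter ``l``
moves only the third (largest) wave, emulating trial-to-trial latency
variability of a late component while the first two are essentially
fixed.

The background EEG is an AR(4) process driven by Gaussian white noise,

    q(t) = 1.5084 q(t-1) - 0.1587 q(t-2) - 0.3109 q(t-3) - 0.0510 q(t-4) + w(t),

a stationary but near-unit-root, strongly low-frequency process (the
characteristic polynomial evaluates to 0.0122 at z = 1), which makes it
a far harsher disturbance than white noise at the same power.

Trials are generated by rescaling independent EEG realizations so that
the epoch-wide power ratio to the (fixed, noise-free) EP hits a target
SNR exactly, then adding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sps

from .exceptions import DimensionError
from .signal_core import Epoch, SampledSignal, add_signals

__all__ = [
    "ReferenceSpec",
    "EEGSimSpec",
    "TrialBatchSpec",
    "BatchTruth",
    "make_reference",
    "simulate_eeg",
    "mix_at_snr",
    "generate_batch",
]


@dataclass(frozen=True)
class ReferenceSpec:
    """Parameters of the three-lobe sinc reference EP.

    ``centers`` are in the argument units of the sinc (the third one is
    shifted by ``l``); ``rate`` is in samples per time unit and
    ``duration`` in time units.  Defaults give a 1000-sample epoch
    covering t in [0, 10).
    """

    amplitudes: tuple[float, ...] = (0.25, 0.5, 1.0)
    centers: tuple[float, ...] = (8.0, 16.0, 24.0)
    scale: float = 0.13 * math.pi
    arg_gain: float = 4.0
    l: float = 0.0
    rate: float = 100.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.centers):
            raise ValueError("amplitudes and centers must have equal length")
        if not (self.rate > 0 and self.duration > 0):
            raise ValueError("rate and duration must be positive")

    def peak_time(self, q: int) -> float:
        """Analytic peak time of component q (l applies to the last one)."""
        c = self.centers[q]
        if q == len(self.centers) - 1:
            c = c - self.l
        return c / self.arg_gain


@dataclass(frozen=True)
class EEGSimSpec:
    """AR(4) background-EEG generator settings."""

    ar_coeffs: tuple[float, ...] = (1.5084, -0.1587, -0.3109, -0.0510)
    innovation_sd: float = 1.0
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be non-negative")


@dataclass(frozen=True)
class TrialBatchSpec:
    """A batch of single-trial observations at one (SNR, l) condition."""

    n_trials: int = 100
    snr_db: float = 0.0
    l: float = 0.0
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    eeg: EEGSimSpec = field(default_factory=EEGSimSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class BatchTruth:
    """Ground truth shared by all trials of a batch."""

    ep: SampledSignal
    third_latency: float  # analytic peak time of the last component, time units


def _sinc(x: np.ndarray) -> np.ndarray:
    # normalized sinc, sin(pi x)/(pi x); keeps the three lobes separated
    return np.sinc(np.asarray(x))


def make_reference(spec: ReferenceSpec) -> SampledSignal:
    """Evaluate the sinc-sum reference EP on the sampled grid."""
    t = np.arange(round(spec.duration * spec.rate)) / spec.rate
    u = np.zeros_like(t)
    last = len(spec.centers) - 1
    for q, (amp, c) in enumerate(zip(spec.amplitudes, spec.centers)):
        if q == last:
            c = c - spec.l
        u += amp * _sinc(spec.scale * (spec.arg_gain * t - c))
    return SampledSignal(u, rate=spec.rate, t0=0.0)


def simulate_eeg(n_samples: int, spec: EEGSimSpec) -> SampledSignal:
    """One realization of the AR(4) background EEG.

    The recursion is run from a zero state for ``burn_in`` extra samples
    which are discarded, so the returned stretch is effectively
    stationary.  Fully determined by ``spec.seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(spec.seed)
    w = rng.standard_normal(n_samples + spec.burn_in) * spec.innovation_sd
    a = np.concatenate(([1.0], -np.asarray(spec.ar_coeffs, dtype=float)))
    q = _sps.lfilter([1.0], a, w)
    return SampledSignal(q[spec.burn_in :], rate=1.0)


def mix_at_snr(
    ep: SampledSignal, eeg: SampledSignal, snr_db: float
) -> tuple[SampledSignal, SampledSignal]:
    """Rescale noise so that measure_snr(ep, noise) == snr_db exactly.

    Returns ``(observation, scaled_noise)`` with
    observation = ep + scaled_noise.
    """
    if ep.n != eeg.n:
        raise DimensionError(f"length mismatch: {ep.n} vs {eeg.n}")
    ps = float(np.mean(ep.samples**2))
    pe = float(np.mean(eeg.samples**2))
    if ps == 0.0 or pe == 0.0:
        raise ValueError("both signal and noise must have nonzero power")
    gain = math.sqrt(ps / (pe * 10.0 ** (snr_db / 10.0)))
    noise = ep.with_samples(gain * eeg.samples)
    return add_signals(ep, noise), noise


def generate_batch(spec: TrialBatchSpec) -> tuple[list[Epoch], BatchTruth]:
    """Generate ``n_trials`` observations sharing one true EP.

    Every trial mixes the same noise-free reference (at the batch's
    ``l``) with an independent AR(4) EEG realization rescaled to
    ``snr_db``.  Child seeds are spawned deterministically from
    ``spec.seed``, so the batch is bit-reproducible.
    """
    ref_spec = replace(spec.reference, l=spec.l)
    ep = make_reference(ref_spec)
    ep = SampledSignal(ep.samples, rate=ep.rate, t0=ep.t0)
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_trials)
    trials: list[Epoch] = []
    for i in range(spec.n_trials):
        eeg_spec = replace(spec.eeg, seed=int(seeds[i]))
        eeg = simulate_eeg(ep.n, eeg_spec)
        eeg = ep.with_samples(eeg.samples)  # carry the EP's rate/t0
        y, _ = mix_at_snr(ep, eeg, spec.snr_db)
        trials.append(Epoch(signal=y, trial_index=i, stimulus_onset=0.0))
    truth = BatchTruth(ep=ep, third_latency=ref_spec.peak_time(len(ref_spec.centers) - 1))
    return trials, truth
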