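"""Decompose an averaged reference EP (AREP) into component subtemplates.

An evoked-potential complex is a superposition of deflections
(components) with distinct latencies and amplitudes.  The averaged
reference EP is split into one reference waveform per component by
detecting its prominent extrema and multiplying the AREP with a taper
(Hamming or Blackman) centred on each peak.  Each subtemplate keeps the
full epoch length, zero outside its window, so downstream stages can
treat it as a time-aligned input channel.

Peak width is not prescribed by the underlying model; by default the
window half-width is the distance to the nearest flanking zero crossing
(symmetrized to the smaller side), with half-prominence and fixed-width
rules available.  Both positive and negative extrema count as
components, since real ERPs carry N- and P-deflections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as _sps

from .exceptions import DegenerateWindowError, EmptyDecompositionError
from .signal_core import SampledSignal

__all__ = [
    "Subtemplate",
    "DecompositionConfig",
    "detect_component_peaks",
    "extract_subtemplate",
    "decompose_template",
]

WindowKind = Literal["hamming", "blackman"]


@dataclass(frozen=True)
class Subtemplate:
    """One component's reference waveform u_q.

    ``waveform`` has the AREP's length and rate and is zero outside the
    component window.
    """

    waveform: SampledSignal
    peak_index: int
    peak_sign: int  # +1 or -1
    window_center: int
    window_halfwidth: int
    window_kind: str = "hamming"

    def __post_init__(self) -> None:
        if self.peak_sign not in (-1, 1):
            raise ValueError("peak_sign must be +1 or -1")
        lo = self.window_center - self.window_halfwidth
        hi = self.window_center + self.window_halfwidth
        if not (lo <= self.peak_index <= hi):
            raise ValueError("peak_index outside the window support")


@dataclass(frozen=True)
class DecompositionConfig:
    """Peak-selection and windowing rules for template decomposition."""

    window_kind: WindowKind = "hamming"
    min_prominence: float = 0.2  # fraction of AREP peak-to-peak range
    max_components: int = 8
    halfwidth_rule: Literal["zero_crossing", "half_prominence", "fixed"] = (
        "zero_crossing"
    )
    fixed_halfwidth: int = 0
    signs: Literal["both", "positive", "negative"] = "both"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_prominence < 1.0):
            raise ValueError("min_prominence must be in (0, 1)")
        if self.max_components < 1:
            raise ValueError("max_components must be positive")


def detect_component_peaks(
    arep: SampledSignal, cfg: DecompositionConfig | None = None
) -> list[tuple[int, int, float]]:
    """Find prominent extrema of either sign in the AREP.

    Returns ``(peak_index, peak_sign, prominence)`` triples sorted by
    time.  A peak qualifies when its prominence is at least
    ``min_prominence`` times the AREP's peak-to-peak range; if more than
    ``max_components`` qualify, the most prominent win.
    """
    cfg = cfg or DecompositionConfig()
    x = arep.samples
    if x.size < 3:
        raise EmptyDecompositionError("AREP too short for peak detection")
    rng = float(np.ptp(x))
    if rng == 0.0:
        raise EmptyDecompositionError("flat AREP: no extrema")
    threshold = cfg.min_prominence * rng
    found: list[tuple[int, int, float]] = []
    signs = {"both": (1, -1), "positive": (1,), "negative": (-1,)}[cfg.signs]
    for sign in signs:
        idx, props = _sps.find_peaks(sign * x, prominence=threshold)
        found.extend(
            (int(i), sign, float(p)) for i, p in zip(idx, props["prominences"])
        )
    if not found:
        raise EmptyDecompositionError("no peak exceeds the prominence threshold")
    if len(found) > cfg.max_components:
        found.sort(key=lambda t: (-t[2], t[0]))
        found = found[: cfg.max_components]
    found.sort(key=lambda t: t[0])
    return found


def _zero_crossing_halfwidth(x: np.ndarray, peak: int, sign: int) -> int:
    """Distance to the nearest flanking zero crossing, min over sides.

    A side with no crossing contributes its distance to the epoch
    boundary instead; asymmetric distances are symmetrized to the
    smaller one.
    """
    v = sign * x
    left = peak
    while left > 0 and v[left - 1] > 0:
        left -= 1
    right = peak
    while right < x.size - 1 and v[right + 1] > 0:
        right += 1
    return min(peak - left, right - peak)


def extract_subtemplate(
    arep: SampledSignal,
    peak: tuple[int, int] | tuple[int, int, float],
    cfg: DecompositionConfig | None = None,
) -> Subtemplate:
    """Window the AREP around one detected peak.

    The window is centred on the peak; its half-width follows
    ``cfg.halfwidth_rule``.  The subtemplate waveform is the elementwise
    product of the AREP and the taper, zero elsewhere, truncated at the
    epoch boundaries.
    """
    cfg = cfg or DecompositionConfig()
    index, sign = int(peak[0]), int(peak[1])
    x = arep.samples
    if cfg.halfwidth_rule == "fixed":
        hw = int(cfg.fixed_halfwidth)
    elif cfg.halfwidth_rule == "half_prominence":
        widths = _sps.peak_widths(sign * x, [index], rel_height=0.5)[0]
        hw = max(int(round(widths[0] / 2.0)), 1)
    else:
        hw = _zero_crossing_halfwidth(x, index, sign)
    if hw < 1:
        raise DegenerateWindowError(f"zero-width window at sample {index}")
    win = np.hamming(2 * hw + 1) if cfg.window_kind == "hamming" else np.blackman(
        2 * hw + 1
    )
    lo = max(index - hw, 0)
    hi = min(index + hw, x.size - 1)
    out = np.zeros_like(x)
    out[lo : hi + 1] = x[lo : hi + 1] * win[lo - (index - hw) : hi - (index - hw) + 1]
    return Subtemplate(
        waveform=arep.with_samples(out),
        peak_index=index,
        peak_sign=sign,
        window_center=index,
        window_halfwidth=hw,
        window_kind=cfg.window_kind,
    )


def decompose_template(
    arep: SampledSignal, cfg: DecompositionConfig | None = None
) -> list[Subtemplate]:
    """Split the AREP into per-component subtemplates, in temporal order."""
    cfg = cfg or DecompositionConfig()
    peaks = detect_component_peaks(arep, cfg)
    return [extract_subtemplate(arep, p, cfg) for p in peaks]
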