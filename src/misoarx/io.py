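"""File I/O: delimited-text trials and waveforms, optional EDF epoching.

The primary on-disk format is plain delimited text with a JSON sidecar
(``<file>.json``) carrying the sampling metadata — simple, diffable and
language-neutral.  Trials files hold one trial per row; waveform files
hold one sample per line.  The sidecar declares the row count, so a
silently truncated file is rejected.

EDF reading (via :mod:`mne`, imported lazily) is an optional capability
for epoching continuous recordings around annotated events; the core
package never depends on a binary format.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import FormatError
from .signal_core import Epoch, SampledSignal

__all__ = [
    "RunConfig",
    "write_trials",
    "read_trials",
    "write_waveform",
    "read_waveform",
    "read_edf_epochs",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


@dataclass(frozen=True)
class RunConfig:
    """All per-stage settings of one run, as a single JSON document.

    Serialization round-trips losslessly (``from_json(to_json(c)) == c``)
    so every artifact can be regenerated bit for bit from the config
    written beside it.  Tuples inside the nested configs are restored
    on load (JSON has no tuple type).
    """

    seed: int = 0
    out_dir: str = "."
    decomposition: "DecompositionConfig" = None  # type: ignore[assignment]
    fit: "FitConfig" = None  # type: ignore[assignment]
    reference: "ReferenceSpec" = None  # type: ignore[assignment]
    eeg: "EEGSimSpec" = None  # type: ignore[assignment]
    shift_range: int | None = None
    tolerance: float = 0.25

    def __post_init__(self) -> None:
        from .model import FitConfig
        from .simulate import EEGSimSpec, ReferenceSpec
        from .templates import DecompositionConfig

        defaults = {
            "decomposition": DecompositionConfig,
            "fit": FitConfig,
            "reference": ReferenceSpec,
            "eeg": EEGSimSpec,
        }
        for name, cls in defaults.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, cls())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        from .model import FitConfig
        from .simulate import EEGSimSpec, ReferenceSpec
        from .templates import DecompositionConfig

        raw = json.loads(text)

        def deep_tuple(value):
            if isinstance(value, list):
                return tuple(deep_tuple(v) for v in value)
            return value

        def build(klass, payload):
            names = {f.name for f in dataclasses.fields(klass)}
            return klass(
                **{k: deep_tuple(v) for k, v in payload.items() if k in names}
            )

        return cls(
            seed=int(raw["seed"]),
            out_dir=raw["out_dir"],
            decomposition=build(DecompositionConfig, raw["decomposition"]),
            fit=build(FitConfig, raw["fit"]),
            reference=build(ReferenceSpec, raw["reference"]),
            eeg=build(EEGSimSpec, raw["eeg"]),
            shift_range=raw.get("shift_range"),
            tolerance=float(raw.get("tolerance", 0.25)),
        )


def write_trials(
    path: str | Path,
    epochs: list[Epoch],
    extra_metadata: dict | None = None,
) -> None:
    """Write epochs as a delimited-text matrix plus a JSON sidecar."""
    path = Path(path)
    if not epochs:
        raise ValueError("no epochs to write")
    rate = epochs[0].signal.rate
    t0 = epochs[0].signal.t0
    n = epochs[0].signal.n
    for ep in epochs:
        if ep.signal.n != n or ep.signal.rate != rate:
            raise FormatError("epochs must share length and rate")
    mat = np.vstack([ep.signal.samples for ep in epochs])
    np.savetxt(path, mat, fmt="%.17g", delimiter="\t")
    meta = {
        "rate": rate,
        "t0": t0,
        "n_trials": len(epochs),
        "n_samples": n,
        "stimulus_onsets": [ep.stimulus_onset for ep in epochs],
    }
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trials(path: str | Path) -> tuple[list[Epoch], dict]:
    """Read a trials matrix written by :func:`write_trials`.

    Raises :class:`FormatError` naming the offending line for ragged
    rows, non-numeric cells, a missing sidecar/rate, or a row count
    that does not match the sidecar's declaration.
    """
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if "rate" not in meta or not (float(meta["rate"]) > 0):
        raise FormatError("sidecar must declare a positive 'rate'")
    rate = float(meta["rate"])
    t0 = float(meta.get("t0", 0.0))
    rows: list[np.ndarray] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.split()
            try:
                row = np.array([float(c) for c in cells])
            except ValueError as exc:
                raise FormatError(f"non-numeric value at line {lineno}") from exc
            if width is None:
                width = row.size
            elif row.size != width:
                raise FormatError(
                    f"ragged row at line {lineno}: {row.size} columns, expected {width}"
                )
            rows.append(row)
    declared = meta.get("n_trials")
    if declared is not None and int(declared) != len(rows):
        raise FormatError(
            f"sidecar declares {declared} trials but file has {len(rows)} rows"
        )
    onsets = meta.get("stimulus_onsets") or [0.0] * len(rows)
    epochs = [
        Epoch(
            signal=SampledSignal(row, rate=rate, t0=t0),
            trial_index=i,
            stimulus_onset=float(onsets[i]) if i < len(onsets) else 0.0,
        )
        for i, row in enumerate(rows)
    ]
    return epochs, meta


def write_waveform(
    path: str | Path, signal: SampledSignal, extra_metadata: dict | None = None
) -> None:
    """Write a single waveform, one sample per line, with a sidecar."""
    path = Path(path)
    np.savetxt(path, signal.samples, fmt="%.17g")
    meta = {"rate": signal.rate, "t0": signal.t0, "n_samples": signal.n}
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_waveform(path: str | Path) -> tuple[SampledSignal, dict]:
    """Read a waveform written by :func:`write_waveform`."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if "rate" not in meta:
        raise FormatError("sidecar must declare 'rate'")
    try:
        samples = np.loadtxt(path, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in {path}") from exc
    if meta.get("n_samples") is not None and int(meta["n_samples"]) != samples.size:
        raise FormatError("sample count does not match sidecar declaration")
    return SampledSignal(samples, rate=float(meta["rate"]), t0=float(meta.get("t0", 0.0))), meta


def read_edf_epochs(
    path: str | Path,
    event_code: str,
    window: tuple[float, float],
    channel: str | None = None,
) -> list[Epoch]:
    """Epoch an EDF(+) recording around annotated events.

    ``window = (pre_s, post_s)`` is seconds around each event onset; the
    epoch covers the half-open interval [onset - pre, onset + post).
    Events are EDF+ annotations whose description equals ``event_code``.
    Events too close to the file edge are skipped with a warning.
    """
    import mne  # optional dependency, imported lazily

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = raw.ch_names
    if channel is None:
        channel = labels[0]
    if channel not in labels:
        raise FormatError(
            f"channel {channel!r} not found; available: {labels}"
        )
    data = raw.get_data(picks=[channel])[0]
    rate = float(raw.info["sfreq"])
    pre_s, post_s = window
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    onsets = [
        float(a["onset"])
        for a in raw.annotations
        if a["description"] == event_code
    ]
    if not onsets:
        raise FormatError(
            f"no events with code {event_code!r}; available: "
            f"{sorted(set(raw.annotations.description))}"
        )
    epochs: list[Epoch] = []
    for i, onset in enumerate(onsets):
        k = int(round(onset * rate))
        lo, hi = k - n_pre, k + n_post
        if lo < 0 or hi > data.size:
            warnings.warn(
                f"event at {onset:.3f}s too close to the file edge; skipped",
                stacklevel=2,
            )
            continue
        sig = SampledSignal(data[lo:hi], rate=rate, t0=-pre_s)
        epochs.append(Epoch(signal=sig, trial_index=i, stimulus_onset=float(pre_s)))
    return epochs
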