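"""Shared fixtures: the benchmark reference, its decomposition, helpers."""

from __future__ import annotations

import numpy as np
import pytest

from misoarx import (
    DecompositionConfig,
    ReferenceSpec,
    SampledSignal,
    decompose_template,
    make_reference,
)


@pytest.fixture(scope="session")
def reference() -> SampledSignal:
    """The l = 0 three-lobe sinc reference on the default 1000-sample grid."""
    return make_reference(ReferenceSpec())


@pytest.fixture(scope="session")
def subtemplates(reference):
    """Positive-peak decomposition of the reference (the benchmark template)."""
    return decompose_template(reference, DecompositionConfig(signs="positive"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def gaussian_bump(n: int, center: int, width: float, amplitude: float = 1.0,
                  rate: float = 100.0) -> SampledSignal:
    """An isolated smooth bump — a convenient synthetic 'component'."""
    i = np.arange(n)
    return SampledSignal(
        amplitude * np.exp(-0.5 * ((i - center) / width) ** 2), rate=rate
    )
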