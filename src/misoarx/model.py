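"""Shared-denominator MISO-ARX identification and EP reconstruction.

The single-trial measurement is modelled as

    y(t) = sum_q B_q(z^-1) u_q(t) / A(z^-1)  +  w(t) / A(z^-1),

one ARMA-filtered, delayed subtemplate per EP component plus AR-filtered
white noise, with a single AR polynomial A shared between the EP
components and the EEG.  Multiplying through by A makes the model linear
in the parameters,

    y(t) = sum_i a_i y(t-i) + sum_q sum_j b_j^q u_q(t - j - d_q) + w(t),

so ordinary least squares on the lagged-regressor matrix is the primary
solver; a plain recursive-least-squares variant (forgetting factor 1) is
provided and converges to the OLS solution on stationary data.

The integer delays d_q are *not* free least-squares parameters: they
come from the sparse-coding lag pre-estimation and are optionally
refined by a bounded exhaustive search (coordinate-wise over the
components, two sweeps) that can only decrease the residual sum of
squares.  The reconstructed EP is s_hat = sum_q B_q u_q / A and the
residual e_hat = y - s_hat is the EEG estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import AllUndetectedError, UnderdeterminedError
from .lags import LagEstimate
from .signal_core import (
    ARPolynomial,
    MAWithDelay,
    SampledSignal,
    filter_arma,
    shift_samples,
)
from .templates import Subtemplate

__all__ = [
    "MISOARXModel",
    "FitConfig",
    "TrialEstimate",
    "build_regression",
    "fit",
    "fit_arx_baseline",
    "select_orders_fpe",
    "subtemplate_from_arep",
]


@dataclass(frozen=True)
class MISOARXModel:
    """Identified model: shared AR polynomial plus per-component numerators.

    ``component_indices`` maps each numerator back to its index in the
    original subtemplate list (undetected components are excluded from
    the model).
    """

    shared_a: ARPolynomial
    numerators: tuple[MAWithDelay, ...]
    noise_variance: float
    component_indices: tuple[int, ...] = ()
    ridge_fallback: bool = False

    def __post_init__(self) -> None:
        if len(self.numerators) < 1:
            raise ValueError("model needs at least one component")
        if not self.component_indices:
            object.__setattr__(
                self, "component_indices", tuple(range(len(self.numerators)))
            )

    @property
    def Q(self) -> int:
        return len(self.numerators)


@dataclass(frozen=True)
class FitConfig:
    """Orders, delay-refinement and solver choices for one fit.

    ``n`` is the shared AR order (default 4, matching an AR(4) EEG
    background); ``m`` the MA order per component (scalar or per-q
    sequence, default 3).  ``delay_refine_radius`` bounds the exhaustive
    integer search around the sparse-coding lags (0 disables it).
    """

    n: int = 4
    m: int | tuple[int, ...] = 3
    delay_refine_radius: int = 3
    solver: str = "ols"  # "ols" | "rls"
    order_selection: str = "fixed"  # "fixed" | "fpe"
    fpe_grid: tuple[tuple[int, int], ...] = ()
    ridge_scale: float = 1e-8

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("AR order n must be >= 0")
        ms = (self.m,) if isinstance(self.m, int) else tuple(self.m)
        if any(m < 1 for m in ms):
            raise ValueError("MA order m must be >= 1")
        if self.delay_refine_radius < 0:
            raise ValueError("delay_refine_radius must be >= 0")
        if self.solver not in ("ols", "rls"):
            raise ValueError("solver must be 'ols' or 'rls'")

    def orders_for(self, n_components: int) -> tuple[int, ...]:
        if isinstance(self.m, int):
            return (self.m,) * n_components
        if len(self.m) != n_components:
            raise ValueError("per-component m length mismatch")
        return tuple(self.m)


@dataclass(frozen=True)
class TrialEstimate:
    """Reconstruction of one trial: EP, per-component parts, residual.

    ``components`` has one entry per *original* subtemplate; entries for
    components dropped from the model are all-zero.  By construction
    ``ep`` is the elementwise sum of ``components`` and
    ``ep + residual`` reproduces the measurement exactly.
    """

    ep: SampledSignal
    components: tuple[SampledSignal, ...]
    residual: SampledSignal
    model: MISOARXModel
    lags_used: LagEstimate


def _design(
    y: np.ndarray,
    inputs: list[np.ndarray],
    delays: list[int],
    n: int,
    ms: tuple[int, ...],
    t_start: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged-regressor matrix and target for rows t_start..N-1."""
    rows = slice(t_start, y.size)
    cols: list[np.ndarray] = []
    for i in range(1, n + 1):
        cols.append(shift_samples(y, i)[rows])
    for u, d, m in zip(inputs, delays, ms):
        for j in range(m):
            cols.append(shift_samples(u, d + j)[rows])
    X = np.column_stack(cols) if cols else np.empty((y.size - t_start, 0))
    return X, y[rows]


def _t_start(n: int, delays: list[int], ms: tuple[int, ...]) -> int:
    depth = max((d + m - 1 for d, m in zip(delays, ms)), default=0)
    return max(n, depth, 0)


def _solve_ols(X: np.ndarray, t: np.ndarray, ridge_scale: float) -> tuple[np.ndarray, bool]:
    theta, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
    if rank < X.shape[1]:
        p = X.shape[1]
        lam = ridge_scale * float(np.trace(X.T @ X)) / max(p, 1)
        theta = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ t)
        warnings.warn("rank-deficient design; ridge fallback used", stacklevel=3)
        return theta, True
    return theta, False


def _solve_rls(X: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Recursive least squares, forgetting factor 1, zero prior."""
    p = X.shape[1]
    theta = np.zeros(p)
    P = np.eye(p) * 1e6
    for k in range(X.shape[0]):
        x = X[k]
        Px = P @ x
        g = Px / (1.0 + x @ Px)
        theta = theta + g * (t[k] - x @ theta)
        P = P - np.outer(g, Px)
    return theta


def build_regression(
    y: SampledSignal,
    subtemplates: list[Subtemplate],
    lags: LagEstimate,
    cfg: FitConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the linear-in-parameters regression for one trial.

    Target y(t) for t = t_start..N-1; columns are the n lagged outputs
    followed, per detected component q, by u_q(t-d_q) .. u_q(t-d_q-m_q+1).
    Out-of-range input samples are zero.
    """
    cfg = cfg or FitConfig()
    detected = lags.detected_indices()
    if not detected:
        raise AllUndetectedError("no detected component to regress on")
    if len(detected) < len(subtemplates):
        warnings.warn(
            f"dropping undetected components {sorted(set(range(len(subtemplates))) - set(detected))}",
            stacklevel=2,
        )
    inputs = [subtemplates[q].waveform.samples for q in detected]
    delays = [int(lags.shifts[q]) for q in detected]
    ms = cfg.orders_for(len(subtemplates))
    ms = tuple(ms[q] for q in detected)
    t0 = _t_start(cfg.n, delays, ms)
    X, t = _design(y.samples, inputs, delays, cfg.n, ms, t0)
    if X.shape[0] < X.shape[1]:
        raise UnderdeterminedError(
            f"{X.shape[0]} rows for {X.shape[1]} parameters"
        )
    return X, t


def _refine_delays(
    y: np.ndarray,
    inputs: list[np.ndarray],
    delays: list[int],
    n: int,
    ms: tuple[int, ...],
    radius: int,
    ridge_scale: float,
) -> list[int]:
    """Coordinate-wise exhaustive delay search, two sweeps.

    The residual sum of squares is always evaluated on the same fixed
    row range (deep enough for every candidate), so accepting a
    candidate can never increase it.
    """
    if radius == 0:
        return delays
    t0 = max(
        n, max(d + radius + m - 1 for d, m in zip(delays, ms)), 0
    )

    def rss(ds: list[int]) -> float:
        X, t = _design(y, inputs, ds, n, ms, t0)
        theta, _ = _solve_ols(X, t, ridge_scale)
        r = t - X @ theta
        return float(r @ r)

    best = list(delays)
    best_rss = rss(best)
    for _sweep in range(2):
        for q in range(len(best)):
            for cand in range(delays[q] - radius, delays[q] + radius + 1):
                if cand == best[q]:
                    continue
                trial = list(best)
                trial[q] = cand
                val = rss(trial)
                if val < best_rss:
                    best, best_rss = trial, val
    return best


def fit(
    y: SampledSignal,
    subtemplates: list[Subtemplate],
    lags: LagEstimate,
    cfg: FitConfig | None = None,
) -> TrialEstimate:
    """Identify the MISO-ARX model for one trial and reconstruct the EP.

    Parameters minimize the innovation sum of squares of the
    linear-in-parameters form; each component is then reconstructed by
    ARMA filtering its subtemplate, s_q = B_q u_q / A, and the EP is
    their sum.  ``noise_variance`` is the regression's residual mean
    square.
    """
    cfg = cfg or FitConfig()
    detected = lags.detected_indices()
    if not detected:
        raise AllUndetectedError("no detected component to fit")
    inputs = [subtemplates[q].waveform.samples for q in detected]
    delays = [int(lags.shifts[q]) for q in detected]
    ms_all = cfg.orders_for(len(subtemplates))
    ms = tuple(ms_all[q] for q in detected)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # refinement reuses the OLS path
        delays = _refine_delays(
            y.samples, inputs, delays, cfg.n, ms, cfg.delay_refine_radius,
            cfg.ridge_scale,
        )

    t0 = _t_start(cfg.n, delays, ms)
    X, t = _design(y.samples, inputs, delays, cfg.n, ms, t0)
    if X.shape[0] < X.shape[1]:
        raise UnderdeterminedError(f"{X.shape[0]} rows for {X.shape[1]} parameters")
    if len(detected) < len(subtemplates):
        warnings.warn(
            f"dropping undetected components {sorted(set(range(len(subtemplates))) - set(detected))}",
            stacklevel=2,
        )

    ridge_used = False
    if cfg.solver == "rls":
        theta = _solve_rls(X, t)
    else:
        theta, ridge_used = _solve_ols(X, t, cfg.ridge_scale)
    resid = t - X @ theta
    noise_var = float(resid @ resid) / max(X.shape[0], 1)

    a = ARPolynomial(theta[: cfg.n])
    numerators: list[MAWithDelay] = []
    pos = cfg.n
    for d, m in zip(delays, ms):
        numerators.append(MAWithDelay(theta[pos : pos + m], delay=d))
        pos += m
    model = MISOARXModel(
        shared_a=a,
        numerators=tuple(numerators),
        noise_variance=noise_var,
        component_indices=tuple(detected),
        ridge_fallback=ridge_used,
    )

    zero = y.with_samples(np.zeros(y.n))
    components: list[SampledSignal] = [zero] * len(subtemplates)
    for q, num in zip(detected, numerators):
        components[q] = filter_arma(subtemplates[q].waveform, num, a)
    ep = y.with_samples(np.sum([c.samples for c in components], axis=0))
    residual = y.with_samples(y.samples - ep.samples)
    used = LagEstimate(
        shifts=np.array(
            [delays[detected.index(q)] if q in detected else 0
             for q in range(len(subtemplates))],
            dtype=int,
        ),
        coefficients=lags.coefficients.copy(),
        detected=lags.detected.copy(),
    )
    return TrialEstimate(
        ep=ep, components=tuple(components), residual=residual,
        model=model, lags_used=used,
    )


def subtemplate_from_arep(arep: SampledSignal) -> Subtemplate:
    """Wrap the whole (undecomposed) AREP as a single pseudo-subtemplate."""
    peak = int(np.argmax(np.abs(arep.samples)))
    sign = 1 if arep.samples[peak] >= 0 else -1
    return Subtemplate(
        waveform=arep,
        peak_index=peak,
        peak_sign=sign,
        window_center=peak,
        window_halfwidth=arep.n,
        window_kind="hamming",
    )


def fit_arx_baseline(
    y: SampledSignal, arep: SampledSignal, cfg: FitConfig | None = None
) -> TrialEstimate:
    """Classical single-input ARX fit with the whole AREP at lag zero.

    This is the conventional single-trial estimator: one undecomposed
    exogenous input, temporal lag assumed to be zero.  It shares every
    code path with :func:`fit` (Q = 1, d = 0), so with those arguments
    the two are identical.
    """
    cfg = cfg or FitConfig()
    if isinstance(cfg.m, tuple):
        cfg = replace(cfg, m=cfg.m[0])
    st = subtemplate_from_arep(arep)
    lag0 = LagEstimate(
        shifts=np.zeros(1, dtype=int),
        coefficients=np.ones(1),
        detected=np.ones(1, dtype=bool),
    )
    return fit(y, [st], lag0, cfg)


def select_orders_fpe(
    y: SampledSignal,
    subtemplates: list[Subtemplate],
    lags: LagEstimate,
    grid: list[tuple[int, int]],
    cfg: FitConfig | None = None,
) -> FitConfig:
    """Pick (n, m) minimizing Akaike's final prediction error.

    FPE = sigma_w^2 (N + p)/(N - p) with p the total parameter count and
    N the regression row count; grid points with N <= p are skipped,
    ties go to the smallest p.  Returns the base config updated with the
    winning orders.
    """
    if not grid:
        raise ValueError("empty order grid")
    base = cfg or FitConfig()
    best: tuple[float, int, tuple[int, int]] | None = None
    nq = len(lags.detected_indices())
    for n, m in grid:
        p = n + m * nq
        cand = replace(base, n=n, m=m)
        try:
            X, t = build_regression(y, subtemplates, lags, cand)
        except UnderdeterminedError:
            continue
        N = X.shape[0]
        if N <= p:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta, _ = _solve_ols(X, t, base.ridge_scale)
        r = t - X @ theta
        sigma2 = float(r @ r) / N
        fpe = sigma2 * (N + p) / (N - p)
        key = (fpe, p, (n, m))
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no feasible grid point")
    n, m = best[2]
    return replace(base, n=n, m=m)
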