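"""Temporal-lag pre-estimation by sparse coding over a shift dictionary.

Classical single-input ARX estimation assumes zero lag between the
template and the trial, which breaks down when component latency varies.
Here each component's lag is pre-estimated: a dictionary D is built
whose atoms are the subtemplates translated left/right by every integer
shift in [-L, L] (unit L2-normalized, zero-padded), and the trial is
sparse-coded over D,

    minimize ||theta||_0  subject to  ||y - D theta||_2 <= eps0,

solved greedily by orthogonal matching pursuit.  The shift of the
selected atom(s) localizes each component in time; the downstream MISO
fit then only needs a small refinement search around these lags.

eps0 reflects the EEG level: by default sqrt(N) times the standard
deviation of a pre-stimulus baseline when one exists, otherwise a
median-absolute-deviation estimate from the whole epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_core import SampledSignal, shift_samples
from .templates import Subtemplate

__all__ = [
    "ShiftDictionary",
    "SparseCode",
    "LagEstimate",
    "build_dictionary",
    "sparse_code",
    "estimate_lags",
    "sequential_pursuit",
    "estimate_background_ar",
    "estimate_lags_prewhitened",
    "default_epsilon0",
]


@dataclass(frozen=True)
class ShiftDictionary:
    """Matrix of shift-translated subtemplate atoms.

    ``atoms`` is (signal_length, n_atoms) with unit-L2 columns;
    ``atom_map[k] = (component_index, shift_in_samples)``.  Shifted
    copies that fall entirely outside the epoch (all-zero columns) are
    dropped.
    """

    atoms: np.ndarray
    atom_map: tuple[tuple[int, int], ...]
    shift_range: tuple[int, int]
    source: tuple[Subtemplate, ...]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def n_components(self) -> int:
        return len(self.source)


@dataclass(frozen=True)
class SparseCode:
    """Result of one OMP run: dense coefficient vector and bookkeeping."""

    coefficients: np.ndarray
    support: tuple[int, ...]  # atom indices in selection order
    residual_norm: float
    epsilon0: float
    max_sparsity_reached: bool = False


@dataclass(frozen=True)
class LagEstimate:
    """Per-component integer lag estimates (samples).

    ``detected[q]`` is False when sparse coding selected no atom of
    component q; the corresponding shift/coefficient are 0.
    """

    shifts: np.ndarray  # int, per component
    coefficients: np.ndarray  # float, per component
    detected: np.ndarray  # bool, per component

    @property
    def n_components(self) -> int:
        return self.shifts.size

    def detected_indices(self) -> list[int]:
        return [q for q in range(self.n_components) if self.detected[q]]


def build_dictionary(
    subtemplates: list[Subtemplate], shift_range_samples: int
) -> ShiftDictionary:
    """Assemble the shift dictionary from component subtemplates.

    For each component q and each shift delta in [-L, L] one atom is the
    subtemplate translated by delta (zero-padded) and L2-normalized.
    """
    if not subtemplates:
        raise ValueError("subtemplate list is empty")
    L = int(shift_range_samples)
    if L < 0:
        raise ValueError("shift range must be non-negative")
    n = subtemplates[0].waveform.n
    rate = subtemplates[0].waveform.rate
    for st in subtemplates:
        if st.waveform.n != n or st.waveform.rate != rate:
            raise ValueError("subtemplates must share length and rate")
    cols: list[np.ndarray] = []
    amap: list[tuple[int, int]] = []
    for q, st in enumerate(subtemplates):
        base = st.waveform.samples
        for delta in range(-L, L + 1):
            atom = shift_samples(base, delta)
            norm = float(np.linalg.norm(atom))
            if norm == 0.0:
                continue
            cols.append(atom / norm)
            amap.append((q, delta))
    return ShiftDictionary(
        atoms=np.column_stack(cols),
        atom_map=tuple(amap),
        shift_range=(-L, L),
        source=tuple(subtemplates),
    )


def sparse_code(
    y: SampledSignal,
    dictionary: ShiftDictionary,
    epsilon0: float,
    max_nonzeros: int | None = None,
    min_nonzeros: int = 0,
) -> SparseCode:
    """Greedy orthogonal matching pursuit.

    Iteratively selects the atom most correlated (in absolute value)
    with the current residual — ties broken toward the lowest atom
    index — refits all selected coefficients by least squares, and stops
    once ``||residual|| <= epsilon0`` or the support reaches
    ``max_nonzeros`` (default: twice the component count).

    ``min_nonzeros`` forces at least that many selections before the
    epsilon0 stop applies (never beyond ``max_nonzeros``).  At very low
    SNR the epoch norm can sit at the noise floor from the start, in
    which case an unforced pursuit would return the empty code and no
    lag information at all.
    """
    D = dictionary.atoms
    if y.n != D.shape[0]:
        raise ValueError("signal length does not match atom length")
    if epsilon0 < 0:
        raise ValueError("epsilon0 must be non-negative")
    if max_nonzeros is None:
        max_nonzeros = 2 * dictionary.n_components
    max_nonzeros = min(max_nonzeros, dictionary.n_atoms)

    target = y.samples
    residual = target.copy()
    support: list[int] = []
    theta_s = np.empty(0)
    rnorm = float(np.linalg.norm(residual))
    min_nonzeros = min(min_nonzeros, max_nonzeros)
    while (rnorm > epsilon0 or len(support) < min_nonzeros) and len(
        support
    ) < max_nonzeros:
        corr = D.T @ residual
        k = int(np.argmax(np.abs(corr)))  # argmax takes the lowest index on ties
        if k in support:
            break  # numerically stagnant; selected atoms already span it
        support.append(k)
        sub = D[:, support]
        theta_s, *_ = np.linalg.lstsq(sub, target, rcond=None)
        residual = target - sub @ theta_s
        rnorm = float(np.linalg.norm(residual))
    coeffs = np.zeros(dictionary.n_atoms)
    if support:
        coeffs[support] = theta_s
    return SparseCode(
        coefficients=coeffs,
        support=tuple(support),
        residual_norm=rnorm,
        epsilon0=float(epsilon0),
        max_sparsity_reached=rnorm > epsilon0 and len(support) >= max_nonzeros,
    )


def estimate_lags(
    y: SampledSignal,
    dictionary: ShiftDictionary,
    epsilon0: float,
    max_nonzeros: int | None = None,
    min_nonzeros: int = 0,
    assignment: str = "atom",
) -> LagEstimate:
    """Read per-component lags off the sparse code.

    Two assignment rules map selected atoms to components:

    * ``"atom"`` (default): each atom belongs to the component it was
      built from; per component, the selected atom with the largest
      absolute coefficient wins and its shift is the lag estimate.
    * ``"amplitude_rank"``: unit-normalized shifted lobes of different
      components are nearly collinear, so an atom's own component label
      is unreliable whenever component positions can cross (a large
      latency shift of one wave).  Instead, picks are ranked by
      absolute coefficient and matched to components ranked by template
      energy — the strongest detection is attributed to the
      highest-amplitude component.  The lag is the pick's absolute
      position minus that component's template peak.

    Components with no selected/assigned atom are flagged undetected.
    """
    if assignment not in ("atom", "amplitude_rank"):
        raise ValueError("assignment must be 'atom' or 'amplitude_rank'")
    code = sparse_code(y, dictionary, epsilon0, max_nonzeros, min_nonzeros)
    Q = dictionary.n_components
    shifts = np.zeros(Q, dtype=int)
    coeffs = np.zeros(Q)
    detected = np.zeros(Q, dtype=bool)
    if assignment == "atom":
        for k in code.support:
            q, delta = dictionary.atom_map[k]
            c = code.coefficients[k]
            if not detected[q] or abs(c) > abs(coeffs[q]):
                shifts[q], coeffs[q], detected[q] = delta, c, True
    else:
        peaks = np.array([st.peak_index for st in dictionary.source])
        energy_rank = np.argsort(
            [-float(np.linalg.norm(st.waveform.samples)) for st in dictionary.source]
        )
        lo, hi = dictionary.shift_range
        halfwidths = np.array([st.window_halfwidth for st in dictionary.source])
        # picks in greedy selection order: the refit coefficients are
        # unreliable strength rankings when selected atoms overlap
        for k in code.support:
            q_atom, delta = dictionary.atom_map[k]
            position = peaks[q_atom] + delta
            # strongest unassigned component whose shift window —
            # widened by its own lobe halfwidth, since overlapping
            # waves drag a correlation peak by up to a lobe width —
            # contains this position
            for q in energy_rank:
                if detected[q]:
                    continue
                shift = int(position - peaks[q])
                if lo - halfwidths[q] <= shift <= hi + halfwidths[q]:
                    shifts[q], coeffs[q] = shift, code.coefficients[k]
                    detected[q] = True
                    break
    if not detected.any():
        warnings.warn("sparse coding detected no component", stacklevel=2)
    return LagEstimate(shifts=shifts, coefficients=coeffs, detected=detected)


def sequential_pursuit(
    y: SampledSignal, dictionary: ShiftDictionary
) -> tuple[LagEstimate, SampledSignal]:
    """Component-ordered structured pursuit: one atom per component.

    Components are visited in decreasing template energy.  For each, the
    atom of *that component's own family* most correlated (in absolute
    value) with the current residual is selected; all selected
    coefficients are refit by least squares and the residual deflated
    before moving to the next component.  Visiting the strongest wave
    first means its lag is estimated on the raw epoch, and deflating it
    removes the main false attractor for the weaker waves.

    Returns the lag estimate (every component detected) and the rough
    EP reconstruction ``sum_q theta_q atom_q`` implied by the picks.
    """
    D = dictionary.atoms
    if y.n != D.shape[0]:
        raise ValueError("signal length does not match atom length")
    Q = dictionary.n_components
    by_component: dict[int, list[int]] = {q: [] for q in range(Q)}
    for k, (q, _delta) in enumerate(dictionary.atom_map):
        by_component[q].append(k)
    energy_order = np.argsort(
        [-float(np.linalg.norm(st.waveform.samples)) for st in dictionary.source]
    )
    target = y.samples
    residual = target.copy()
    picked: list[int] = []
    theta = np.empty(0)
    shifts = np.zeros(Q, dtype=int)
    coeffs = np.zeros(Q)
    chosen_for: dict[int, int] = {}
    detected = np.ones(Q, dtype=bool)
    for q in energy_order:
        if not by_component[int(q)]:
            detected[int(q)] = False
            continue
        fam = np.asarray(by_component[int(q)], dtype=int)
        corr = D[:, fam].T @ residual
        k = int(fam[int(np.argmax(np.abs(corr)))])
        picked.append(k)
        chosen_for[int(q)] = k
        sub = D[:, picked]
        theta, *_ = np.linalg.lstsq(sub, target, rcond=None)
        residual = target - sub @ theta
    for q, k in chosen_for.items():
        shifts[q] = dictionary.atom_map[k][1]
        coeffs[q] = theta[picked.index(k)]
    ep = D[:, picked] @ theta if picked else np.zeros(y.n)
    return LagEstimate(shifts=shifts, coefficients=coeffs, detected=detected), (
        y.with_samples(ep)
    )


def estimate_background_ar(
    y: SampledSignal, order: int = 4, ep_estimate: SampledSignal | None = None
) -> "ARPolynomial":
    """Fit an AR model to the background EEG of one epoch (Burg).

    If a rough EP estimate is supplied it is subtracted first, so the
    fit describes the noise rather than the evoked waveform.  Burg's
    method is used because the simulated (and much real) EEG is
    near-unit-root, where Yule-Walker estimates are badly biased.  An
    unstable fit falls back to the order-0 (identity) polynomial.
    """
    from statsmodels.regression.linear_model import burg as _burg

    from .signal_core import ARPolynomial

    x = y.samples.copy()
    if ep_estimate is not None:
        x = x - ep_estimate.samples
    x = x - x.mean()
    rho, _sigma2 = _burg(x, order=order)
    ar = ARPolynomial(rho)
    return ar if ar.is_stable() else ARPolynomial(np.empty(0))


def estimate_lags_prewhitened(
    y: SampledSignal,
    subtemplates: list[Subtemplate],
    shift_range_samples: int,
    ar_order: int = 4,
    dictionary: ShiftDictionary | None = None,
) -> LagEstimate:
    """Two-pass lag estimation with background-AR prewhitening.

    Pass 1 runs :func:`sequential_pursuit` on the raw epoch; the rough
    EP it implies is subtracted and an AR(``ar_order``) background model
    fitted to the remainder.  Pass 2 whitens both the epoch and the
    subtemplates with that AR polynomial (matched filtering in coloured
    noise) and repeats the pursuit; its lags are returned.  When the AR
    fit is unstable the raw-pass lags are returned unchanged.

    ``dictionary`` may carry a prebuilt raw-domain dictionary for the
    given subtemplates/shift range, to amortize construction over many
    trials.
    """
    from dataclasses import replace as _replace

    raw_dict = dictionary or build_dictionary(subtemplates, shift_range_samples)
    raw_lags, rough = sequential_pursuit(y, raw_dict)
    ar = estimate_background_ar(y, order=ar_order, ep_estimate=rough)
    if ar.order == 0:
        return raw_lags
    y_w = y.with_samples(ar.apply_fir(y.samples))
    subs_w = [
        _replace(st, waveform=st.waveform.with_samples(ar.apply_fir(st.waveform.samples)))
        for st in subtemplates
    ]
    white_dict = build_dictionary(subs_w, shift_range_samples)
    lags, _ = sequential_pursuit(y_w, white_dict)
    return lags


def default_epsilon0(
    y: SampledSignal, baseline: slice | None = None
) -> float:
    """Stopping threshold sqrt(N) * sigma_EEG.

    ``sigma_EEG`` comes from the sample standard deviation of a
    designated pre-stimulus ``baseline`` slice; without one it falls
    back to 1.4826 times the median absolute deviation of the whole
    epoch, which is robust to the embedded EP.
    """
    x = y.samples
    if baseline is not None:
        seg = x[baseline]
        if seg.size < 2:
            raise ValueError("baseline segment too short")
        sigma = float(np.std(seg))
    else:
        sigma = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    return float(np.sqrt(x.size) * sigma)
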