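"""Delay-coordinate embedding and polynomial (multinomial) kernel expansion.

The delay-coordinate MSUA space appends to each population rate vector one
time-lagged copy of every unit's rate, with per-unit lags chosen at the first
minimum of the average cross-correlation with the other units. The O-th-order
expansion space then contains every product of these base variables up to
total degree O; it is accessed implicitly through the inhomogeneous polynomial
kernel k(x, y) = (1 + x·y)^O - 1, whose feature space is exactly the set of
degree-1..O monomials weighted by square-rooted multinomial counts. An
explicit feature map is provided as an oracle for small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb, factorial

import numpy as np

from .preprocess import EpochTimeline, RateMatrix, UNLABELED


@dataclass
class DelaySpec:
    """Per-unit delays (in bins) for the delay-coordinate map."""

    lags: np.ndarray  # one lag per unit, >= 1
    max_lag_frac: float = 0.05

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        if (self.lags < 1).any():
            raise ValueError("all lags must be >= 1 bin")

    @property
    def max_lag(self) -> int:
        return int(self.lags.max())


@dataclass
class DCMatrix:
    """Delay-coordinate MSUA matrix: rows [v_i(t), v_i(t - tau_i)]."""

    values: np.ndarray  # T' x 2n
    row_index: np.ndarray  # indices of rows into the parent RateMatrix
    lags: np.ndarray
    trial_ids: np.ndarray
    labels: np.ndarray | None = None

    @property
    def n_base(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpansionSpec:
    """Order-O multinomial expansion over ``base_dim`` variables."""

    order: int
    base_dim: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.base_dim < 1:
            raise ValueError("base_dim must be >= 1")

    @property
    def ambient_dim(self) -> int:
        """Number of monomials of total degree 1..O: C(base_dim + O, O) - 1."""
        return comb(self.base_dim + self.order, self.order) - 1


@dataclass
class KernelMatrix:
    """Pairwise kernel evaluations standing in for expanded-space dot products."""

    values: np.ndarray
    order: int
    row_labels: np.ndarray | None = None
    col_labels: np.ndarray | None = None
    row_index: np.ndarray | None = None
    col_index: np.ndarray | None = None

    @property
    def shape(self):
        return self.values.shape


# ---------------------------------------------------------------------------
# delay selection


def _phase_of(label: str) -> str:
    if label.startswith("train"):
        return "training"
    if label == "delay":
        return "delay"
    return "test"


def _phase_lengths(timeline: EpochTimeline, trial_ids: np.ndarray) -> list:
    """Length in bins of each task phase (training / delay / test) per trial.

    Epoch labels are grouped into the three maze phases; a phase's length is
    the span from its first to its last labeled bin within the trial
    (unlabeled gaps between same-phase epochs belong to the phase).
    """
    out = []
    trial_ids = np.asarray(trial_ids)
    for trial in dict.fromkeys(trial_ids.tolist()):
        mask = trial_ids == trial
        labs = timeline.labels[mask]
        spans: dict = {}
        for pos, lab in enumerate(labs):
            if lab == UNLABELED:
                continue
            ph = _phase_of(lab)
            lo, hi = spans.get(ph, (pos, pos))
            spans[ph] = (min(lo, pos), max(hi, pos))
        out.extend(hi - lo + 1 for lo, hi in spans.values())
    return out


def _lagged_corr(x: np.ndarray, y: np.ndarray, trial_ids: np.ndarray, lag: int) -> float:
    """Pearson correlation of x(t) with y(t - lag), within-trial pairs only."""
    if lag == 0:
        a, b = x, y
    else:
        ok = np.zeros(len(x), dtype=bool)
        ok[lag:] = trial_ids[lag:] == trial_ids[:-lag]
        a, b = x[ok], y[np.flatnonzero(ok) - lag]
    if len(a) < 3:
        return 0.0
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def select_delays(
    r: RateMatrix, timeline: EpochTimeline, max_lag_frac: float = 0.05
) -> DelaySpec:
    """Pick each unit's lag at the first local minimum of its average
    cross-correlation with the other units' rates.

    Lags are scanned up to ``max_lag_frac`` of the shortest labeled task-phase
    length (in bins); if the average cross-correlation has no interior local
    minimum in that range, the lag falls back to 1 bin.
    """
    n = r.n_units
    if n < 2:
        raise ValueError("delay selection needs at least 2 units")
    phases = _phase_lengths(timeline, r.trial_ids)
    if not phases:
        raise ValueError("phases too short for delay selection")
    l_max = int(np.floor(max_lag_frac * min(phases)))
    if l_max < 1:
        raise ValueError("phases too short for delay selection")

    lags = np.ones(n, dtype=int)
    for i in range(n):
        avg = np.zeros(l_max + 1)
        for tau in range(l_max + 1):
            cs = [
                _lagged_corr(r.values[:, i], r.values[:, j], r.trial_ids, tau)
                for j in range(n)
                if j != i
            ]
            avg[tau] = np.mean(cs)
        chosen = 1
        for tau in range(1, l_max):
            if avg[tau] < avg[tau - 1] and avg[tau] < avg[tau + 1]:
                chosen = tau
                break
        lags[i] = chosen
    return DelaySpec(lags=lags, max_lag_frac=max_lag_frac)


def build_dc_msua(
    r: RateMatrix, d: DelaySpec, timeline: EpochTimeline | None = None
) -> DCMatrix:
    """Append one lagged copy of each unit's rate; drop bins lacking history.

    Row t is (v_1(t), ..., v_n(t), v_1(t - tau_1), ..., v_n(t - tau_n)), built
    per trial so no row mixes bins across trial boundaries. Columns are
    ordered units-then-lagged-units.
    """
    if len(d.lags) != r.n_units:
        raise ValueError("one lag per unit required")
    max_lag = d.max_lag
    rows, index = [], []
    for trial, sl in r.trial_slices():
        block = r.values[sl]
        t_len = block.shape[0]
        if max_lag >= t_len:
            raise ValueError(
                f"lag {max_lag} is not shorter than trial {trial!r} ({t_len} bins)"
            )
        t = np.arange(max_lag, t_len)
        lagged = np.stack(
            [block[t - d.lags[i], i] for i in range(r.n_units)], axis=1
        )
        rows.append(np.concatenate([block[t], lagged], axis=1))
        index.append(np.arange(sl.start, sl.stop)[max_lag:])
    row_index = np.concatenate(index)
    return DCMatrix(
        values=np.concatenate(rows, axis=0),
        row_index=row_index,
        lags=d.lags,
        trial_ids=r.trial_ids[row_index],
        labels=None if timeline is None else timeline.labels[row_index],
    )


# ---------------------------------------------------------------------------
# expansion / kernel


def monomial_exponents(base_dim: int, order: int) -> list:
    """All monomial index tuples of total degree 1..order, graded-lex ordered."""
    out = []
    for deg in range(1, order + 1):
        out.extend(combinations_with_replacement(range(base_dim), deg))
    return out


def explicit_expand(x: np.ndarray, spec: ExpansionSpec) -> np.ndarray:
    """Explicit feature map whose dot products equal :func:`poly_kernel`.

    The coordinate for a degree-k monomial x^a is
    sqrt(C(O, k) * k! / prod(a_i!)) * x^a, i.e. the square root of the weight
    with which the monomial appears in the expansion of (1 + x.y)^O - 1.
    Guarded to small problems; for real data use the kernel path.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != spec.base_dim:
        raise ValueError("vector dimension does not match spec.base_dim")
    if spec.base_dim > 12 or spec.order > 4:
        raise ValueError(
            "explicit expansion guarded to base_dim <= 12 and order <= 4; "
            "use poly_kernel for larger problems"
        )
    feats = np.empty(spec.ambient_dim)
    for pos, idx in enumerate(monomial_exponents(spec.base_dim, spec.order)):
        k = len(idx)
        counts: dict = {}
        for i in idx:
            counts[i] = counts.get(i, 0) + 1
        multi = factorial(k)
        for c in counts.values():
            multi //= factorial(c)
        weight = comb(spec.order, k) * multi
        feats[pos] = np.sqrt(weight) * np.prod(x[list(idx)])
    return feats


def poly_kernel(a: np.ndarray, b: np.ndarray, order: int, **meta) -> KernelMatrix:
    """Inhomogeneous polynomial kernel k(x, y) = (1 + x·y)^order - 1.

    Equals the dot product of the order-O multinomial feature maps of x and y;
    for order 1 it reduces to the plain Gram matrix.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("vector sets must share base dimension")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite inputs to poly_kernel")
    gram = a @ b.T
    values = (1.0 + gram) ** order - 1.0
    return KernelMatrix(values=values, order=order, **meta)
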