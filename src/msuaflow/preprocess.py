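"""Spike-table ingestion, unit quality control, rate estimation and epoch labeling.

Spike trains are convolved with unit-area Gaussian kernels and averaged over
half-open time bins to yield a population firing-rate matrix (the MSUA space).
Task-epoch labels are attached per bin from an event/window table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

logger = logging.getLogger(__name__)

#: Recognized task-epoch labels (a delayed win-shift maze task has choice and
#: reward periods in both a training and a test phase, separated by a delay).
EPOCH_LABELS = (
    "train_choice",
    "train_reward",
    "delay",
    "test_choice",
    "test_reward",
    "error_choice",
)
UNLABELED = "unlabeled"
REWARD_LABELS = ("train_reward", "test_reward")

#: Precedence used to resolve overlapping windows of different kinds.
_PRECEDENCE = {"reward": 3, "choice": 2, "delay": 1, "other": 0}


class SpikeTableError(ValueError):
    """Raised when a spike or event table cannot be parsed."""


def _label_kind(label: str) -> str:
    if label.endswith("reward"):
        return "reward"
    if label.endswith("choice"):
        return "choice"
    if label == "delay":
        return "delay"
    return "other"


@dataclass
class SpikeTrainSet:
    """Per-trial spike times for a set of simultaneously recorded units."""

    trial_id: object
    units: dict  # unit_id -> np.ndarray of non-decreasing spike times (s)
    trial_span: tuple  # (t_start, t_end) in s

    def __post_init__(self) -> None:
        t0, t1 = self.trial_span
        if not t1 > t0:
            raise ValueError("trial_span must have t_end > t_start")
        clean = {}
        for uid, times in self.units.items():
            arr = np.asarray(times, dtype=float)
            arr = np.sort(arr)
            if arr.size and (arr[0] < t0 or arr[-1] > t1):
                raise ValueError(
                    f"unit {uid}: spike times outside trial span {self.trial_span}"
                )
            clean[uid] = arr
        self.units = clean

    @property
    def unit_ids(self) -> list:
        return list(self.units.keys())

    @property
    def duration(self) -> float:
        return self.trial_span[1] - self.trial_span[0]

    def n_spikes(self) -> dict:
        return {uid: len(t) for uid, t in self.units.items()}


@dataclass
class UnitQCReport:
    """Audit trail of the quality-control filter."""

    removed_isi_spikes: dict = field(default_factory=dict)  # unit -> count
    removed_duplicate_units: list = field(default_factory=list)  # (kept, dropped, corr)
    removed_low_rate_units: list = field(default_factory=list)  # (unit, ratio)

    def removed_unit_ids(self) -> set:
        out = {u for _, u, _ in self.removed_duplicate_units}
        out |= {u for u, _ in self.removed_low_rate_units}
        return out


@dataclass
class RateMatrix:
    """Binned, Gaussian-smoothed population firing rates (T x n)."""

    values: np.ndarray  # T x n, spikes/s (or 1/s probability density if normalized)
    bin_width: float  # s
    sigma: float  # s, SD of the smoothing Gaussian
    bin_starts: np.ndarray  # s, time of each bin's left edge within its trial
    unit_ids: list
    trial_ids: np.ndarray  # per-bin trial identifier
    normalized_to_trial: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (bins x units)")
        if (self.values < 0).any():
            raise ValueError("firing rates must be non-negative")
        if len(self.bin_starts) != len(self.values) or len(self.trial_ids) != len(
            self.values
        ):
            raise ValueError("bin_starts/trial_ids length mismatch")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def trial_slices(self) -> list:
        """Contiguous (trial_id, slice) runs in bin order."""
        out = []
        ids = self.trial_ids
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                out.append((ids[start], slice(start, i)))
                start = i
        return out


@dataclass
class EpochTimeline:
    """Per-bin task-epoch labels plus the windows they were derived from."""

    labels: np.ndarray  # per-bin label strings
    event_windows: list  # (label, start_s, end_s, trial_id)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED

    def block_runs(self, trial_ids: np.ndarray) -> list:
        """Maximal runs of constant (trial, label): list of (label, slice)."""
        out = []
        n = len(self.labels)
        start = 0
        for i in range(1, n + 1):
            if (
                i == n
                or self.labels[i] != self.labels[start]
                or trial_ids[i] != trial_ids[start]
            ):
                out.append((self.labels[start], slice(start, i)))
                start = i
        return out


# ---------------------------------------------------------------------------
# loading


def load_spike_table(
    path, trial_span: tuple, trial_id: object = None, sep: str = ","
) -> SpikeTrainSet:
    """Read a delimited spike table with columns ``unit_id,time_s``.

    Rows from other trials (via an optional ``trial_id`` column) are ignored
    when ``trial_id`` is given. Unknown columns are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpikeTableError(f"{path}: cannot parse table: {exc}") from exc
    for col in ("unit_id", "time_s"):
        if col not in df.columns:
            raise SpikeTableError(f"{path}: missing required column '{col}'")
    if trial_id is not None and "trial_id" in df.columns:
        df = df[df["trial_id"] == trial_id]
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() & df["time_s"].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise SpikeTableError(f"{path}: non-numeric time_s at line {line}")
    t0, t1 = trial_span
    out_of_span = (times < t0) | (times > t1)
    if out_of_span.any():
        line = int(df.index[out_of_span][0]) + 2
        raise SpikeTableError(
            f"{path}: spike time outside trial span {trial_span} at line {line}"
        )
    units: dict = {}
    for uid, grp in df.groupby("unit_id", sort=True):
        units[uid] = np.sort(grp["time_s"].to_numpy(dtype=float))
    return SpikeTrainSet(
        trial_id=trial_id if trial_id is not None else 0,
        units=units,
        trial_span=(float(t0), float(t1)),
    )


def _as_trial_list(s) -> list:
    return list(s) if isinstance(s, (list, tuple)) else [s]


# ---------------------------------------------------------------------------
# quality control


def _isi_clean(times: np.ndarray, isi_floor: float) -> tuple:
    """Drop the second spike of every pair closer than ``isi_floor``."""
    if times.size == 0:
        return times, 0
    keep = [times[0]]
    dropped = 0
    for t in times[1:]:
        if t - keep[-1] <= isi_floor:
            dropped += 1
        else:
            keep.append(t)
    return np.asarray(keep), dropped


def _binary_corr(trains: list, unit_ids: list, bin_ms: float = 0.001) -> np.ndarray:
    """Zero-lag Pearson correlation of 1-ms binned spike indicators, pooled."""
    cols = []
    for st in trains:
        t0, t1 = st.trial_span
        n_bins = int(np.ceil((t1 - t0) / bin_ms))
        mat = np.zeros((n_bins, len(unit_ids)), dtype=np.float32)
        for k, uid in enumerate(unit_ids):
            times = st.units.get(uid, np.empty(0))
            if len(times):
                idx = np.minimum(((times - t0) / bin_ms).astype(int), n_bins - 1)
                mat[idx, k] = 1.0
        cols.append(mat)
    stacked = np.concatenate(cols, axis=0)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(stacked, rowvar=False)
    return np.nan_to_num(np.atleast_2d(c))


def qc_filter_units(
    s,
    rates: RateMatrix | None = None,
    isi_floor: float = 0.010,
    dup_corr_max: float = 0.9,
    low_rate_frac: float = 0.02,
):
    """Apply the three unit-quality filters in order.

    1. Remove the second spike of any pair with ISI <= ``isi_floor``
       (unphysiologically short intervals indicate sorting artifacts).
    2. Of any unit pair whose zero-lag 1-ms-binned spike-indicator correlation
       exceeds ``dup_corr_max``, drop the lower-rate unit (likely the same
       neuron captured twice).
    3. Drop units whose mean rate is below ``low_rate_frac`` of the most
       responsive unit's mean rate.

    Accepts a single :class:`SpikeTrainSet` or a list of them (one per trial);
    unit decisions are pooled across trials. Returns the filtered train(s) and
    a :class:`UnitQCReport`.
    """
    trains = _as_trial_list(s)
    single = not isinstance(s, (list, tuple))
    report = UnitQCReport()

    unit_ids = sorted({u for st in trains for u in st.units}, key=str)
    if not unit_ids:
        raise ValueError("no responsive units")

    # 1. ISI cleaning
    cleaned = []
    for st in trains:
        units = {}
        for uid in unit_ids:
            times = st.units.get(uid, np.empty(0))
            kept, dropped = _isi_clean(np.asarray(times, float), isi_floor)
            units[uid] = kept
            if dropped:
                report.removed_isi_spikes[uid] = (
                    report.removed_isi_spikes.get(uid, 0) + dropped
                )
        cleaned.append(SpikeTrainSet(st.trial_id, units, st.trial_span))

    # mean rates pooled over trials (after ISI cleaning)
    total_dur = sum(st.duration for st in cleaned)
    mean_rate = {
        uid: sum(len(st.units[uid]) for st in cleaned) / total_dur for uid in unit_ids
    }

    # 2. duplicate removal
    corr = _binary_corr(cleaned, unit_ids)
    dropped_units: set = set()
    for i in range(len(unit_ids)):
        for j in range(i + 1, len(unit_ids)):
            ui, uj = unit_ids[i], unit_ids[j]
            if ui in dropped_units or uj in dropped_units:
                continue
            if corr[i, j] > dup_corr_max:
                lo, hi = (ui, uj) if mean_rate[ui] <= mean_rate[uj] else (uj, ui)
                dropped_units.add(lo)
                report.removed_duplicate_units.append((hi, lo, float(corr[i, j])))

    # 3. low-rate exclusion
    survivors = [u for u in unit_ids if u not in dropped_units]
    max_rate = max(mean_rate[u] for u in survivors) if survivors else 0.0
    for uid in survivors:
        ratio = mean_rate[uid] / max_rate if max_rate > 0 else 0.0
        if ratio < low_rate_frac:
            dropped_units.add(uid)
            report.removed_low_rate_units.append((uid, float(ratio)))

    keep = [u for u in unit_ids if u not in dropped_units]
    if not keep:
        raise ValueError("no responsive units")

    out = [
        SpikeTrainSet(st.trial_id, {u: st.units[u] for u in keep}, st.trial_span)
        for st in cleaned
    ]
    return (out[0] if single else out), report


# ---------------------------------------------------------------------------
# rate estimation


def estimate_rates(
    s,
    sigma: float = 0.05,
    bin_width: float = 0.2,
    normalize_to_trial: bool = False,
) -> RateMatrix:
    """Gaussian-smoothed spike density averaged over half-open bins.

    For each unit the density is a sum of unit-area Gaussians centered on the
    spikes; the bin value is the mean of this density over ``[t, t+bin_width)``,
    computed exactly from Gaussian CDF differences, so units are spikes/s.
    Gaussian mass falling outside the trial is truncated (not reflected).
    With ``normalize_to_trial`` each unit's density is divided by its integral
    over the trial, turning it into a probability density over time.
    """
    if sigma <= 0 or bin_width <= 0:
        raise ValueError("sigma and bin_width must be positive")
    trains = _as_trial_list(s)
    unit_ids = sorted({u for st in trains for u in st.units}, key=str)

    blocks, starts, tids = [], [], []
    halfwidth = int(np.ceil(6 * sigma / bin_width)) + 1
    for st in trains:
        t0, t1 = st.trial_span
        n_bins = int(np.floor((t1 - t0) / bin_width))
        edges = t0 + bin_width * np.arange(n_bins + 1)
        vals = np.zeros((n_bins, len(unit_ids)))
        for k, uid in enumerate(unit_ids):
            times = np.asarray(st.units.get(uid, ()), dtype=float)
            if times.size == 0:
                continue
            center_bin = np.floor((times - t0) / bin_width).astype(int)
            for off in range(-halfwidth, halfwidth + 1):
                idx = center_bin + off
                ok = (idx >= 0) & (idx < n_bins)
                if not ok.any():
                    continue
                hi = ndtr((edges[idx[ok] + 1] - times[ok]) / sigma)
                lo = ndtr((edges[idx[ok]] - times[ok]) / sigma)
                np.add.at(vals[:, k], idx[ok], hi - lo)
        vals /= bin_width
        if normalize_to_trial:
            integral = vals.sum(axis=0) * bin_width
            integral[integral == 0] = 1.0
            vals = vals / integral
        blocks.append(vals)
        starts.append(edges[:-1] - t0)
        tids.append(np.full(n_bins, st.trial_id, dtype=object))

    return RateMatrix(
        values=np.concatenate(blocks, axis=0),
        bin_width=bin_width,
        sigma=sigma,
        bin_starts=np.concatenate(starts),
        unit_ids=unit_ids,
        trial_ids=np.concatenate(tids),
        normalized_to_trial=normalize_to_trial,
    )


def save_rate_matrix(r: RateMatrix, path) -> None:
    """Persist a RateMatrix to an HDF5 container with its metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=r.values)
        f.create_dataset("bin_starts", data=r.bin_starts)
        f.create_dataset(
            "trial_ids", data=np.asarray([str(t) for t in r.trial_ids], dtype="S")
        )
        f.attrs["bin_width"] = r.bin_width
        f.attrs["sigma"] = r.sigma
        f.attrs["normalized_to_trial"] = r.normalized_to_trial
        f.attrs["unit_ids"] = [str(u) for u in r.unit_ids]


def load_rate_matrix(path) -> RateMatrix:
    """Load a RateMatrix written by :func:`save_rate_matrix`."""
    import h5py

    with h5py.File(path, "r") as f:
        return RateMatrix(
            values=f["values"][()],
            bin_width=float(f.attrs["bin_width"]),
            sigma=float(f.attrs["sigma"]),
            bin_starts=f["bin_starts"][()],
            unit_ids=list(f.attrs["unit_ids"]),
            trial_ids=np.array([t.decode() for t in f["trial_ids"][()]], dtype=object),
            normalized_to_trial=bool(f.attrs["normalized_to_trial"]),
        )


# ---------------------------------------------------------------------------
# epoch timeline


def _windows_from_events(df: pd.DataFrame) -> list:
    """Derive (label, start, end, trial) windows from an event table.

    Rows with an ``end_s`` are explicit windows; rows without one are point
    events: ``*food_cup`` events open a 1.0-s reward window starting 0.2 s
    before the event, ``*arm_choice`` events open a choice window from 1.5 s
    before until 0.5 s after the event or until the next reward window of the
    same trial starts, whichever is earlier.
    """
    windows = []
    has_end = "end_s" in df.columns
    for trial, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("start_s")
        rewards = []
        pending_choices = []
        for _, row in grp.iterrows():
            name = str(row["label_or_event"])
            t = float(row["start_s"])
            end = row["end_s"] if has_end else np.nan
            if has_end and pd.notna(end):
                if name not in EPOCH_LABELS:
                    raise SpikeTableError(f"unknown window label '{name}'")
                windows.append((name, t, float(end), trial))
            elif name.endswith("food_cup"):
                label = (
                    "train_reward" if name.startswith("train") else "test_reward"
                )
                rewards.append((t - 0.2, t + 0.8))
                windows.append((label, t - 0.2, t + 0.8, trial))
            elif name.endswith("arm_choice"):
                if name.startswith("train"):
                    label = "train_choice"
                elif name.startswith("error"):
                    label = "error_choice"
                else:
                    label = "test_choice"
                pending_choices.append((label, t, trial))
            else:
                raise SpikeTableError(f"unknown event type '{name}'")
        for label, t, trial_ in pending_choices:
            end = t + 0.5
            upcoming = [r0 for r0, _ in rewards if t < r0 < end]
            if upcoming:
                end = min(upcoming)
            windows.append((label, t - 1.5, end, trial_))
    return windows


def build_epoch_timeline(events, rates: RateMatrix) -> EpochTimeline:
    """Assign per-bin epoch labels by majority temporal overlap with windows.

    ``events`` may be a path to a CSV with columns
    ``trial_id,label_or_event,start_s[,end_s]`` or an equivalent DataFrame,
    or an already-derived list of ``(label, start, end, trial_id)`` windows.
    A bin is labeled only if the winning label covers more than half of it;
    overlaps between labels are resolved by precedence reward > choice > delay
    (logged as a warning).
    """
    if isinstance(events, (str, Path)):
        events = pd.read_csv(events)
    if isinstance(events, pd.DataFrame):
        for col in ("trial_id", "label_or_event", "start_s"):
            if col not in events.columns:
                raise SpikeTableError(f"event table missing column '{col}'")
        windows = _windows_from_events(events)
    else:
        windows = [(str(l), float(a), float(b), t) for (l, a, b, t) in events]

    dt = rates.bin_width
    labels = np.full(rates.n_bins, UNLABELED, dtype=object)
    by_trial: dict = {}
    for w in windows:
        by_trial.setdefault(w[3], []).append(w)

    for trial, sl in rates.trial_slices():
        wins = by_trial.get(trial, [])
        if not wins:
            continue
        t_lo = rates.bin_starts[sl]
        t_hi = t_lo + dt
        overlap: dict = {}
        for label, a, b, _ in wins:
            ov = np.clip(np.minimum(t_hi, b) - np.maximum(t_lo, a), 0.0, None)
            overlap[label] = overlap.get(label, 0.0) + ov
        lab_names = list(overlap)
        ov_mat = np.stack([overlap[l] for l in lab_names], axis=1)
        multi = (ov_mat > 0).sum(axis=1) > 1
        if multi.any():
            logger.warning(
                "%d bins overlap windows of different labels; precedence "
                "reward > choice > delay applied",
                int(multi.sum()),
            )
        prec = np.array([_PRECEDENCE[_label_kind(l)] for l in lab_names])
        # winner: max overlap; ties by precedence
        score = ov_mat + 1e-9 * prec  # tie-break only; overlaps are >= bin scale
        win = np.argmax(score, axis=1)
        win_ov = ov_mat[np.arange(len(win)), win]
        chosen = np.where(win_ov > dt / 2, np.array(lab_names, object)[win], UNLABELED)
        labels[sl] = chosen

    return EpochTimeline(labels=labels, event_windows=windows)
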