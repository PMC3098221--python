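"""Synthetic multistable-ensemble spike simulator with ground-truth epochs.

The generator emulates a multi-unit recording during a delayed win-shift maze
trial: a low-dimensional latent state follows Ornstein–Uhlenbeck dynamics
pulled toward an epoch-specific fixed point (the attracting state of the
active task epoch), switching fixed points at epoch boundaries:

    dz = lambda * (c_epoch - z) dt + noise_sd dW.

Each epoch's pull target additionally carries a slow circulating component
(radius ``orbit_amplitude``, angular rate ``rotation_rate``, in the plane of
the first two latent dimensions, with a random initial phase per epoch
occurrence), so within an epoch state the population activity cycles through
a sequence of sub-patterns — the cycling orbits and sequential activation
characteristic of attracting neural ensemble states. Epochs of the same kind
in the training and the test phase of the task (the two choice epochs, the
two reward epochs) share the same fixed point but circulate in opposite
directions: like their behavioral counterparts they share all "sensory"
features (identical marginal rate distributions) and differ only in their
internal dynamics, so they can be told apart through interactions of current
and lagged rates but not through any linear readout of the rates themselves.
The circulation also breaks time-reversibility inside the states, which a
pure OU pull (reversible in stationarity) would only violate during the
brief entry transients. Unit firing rates are a rectified-linear readout of
the latent state,
rate_i(t) = max(baseline + (L z(t))_i, 0), and spikes are drawn from an
inhomogeneous Poisson process at 1 ms resolution. Matched null variants
(single shared fixed point; shuffled labels; time inversion) provide
label-uninformative controls with the same marginal statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import EPOCH_LABELS, UNLABELED, SpikeTrainSet

#: Distinct labeled epochs in the default schedule.
_DEFAULT_LABELED = ("train_choice", "train_reward", "delay", "test_choice", "test_reward")


def default_epoch_schedule() -> list:
    """Ordered (label, duration s) schedule mimicking one maze trial.

    Four training choice/reward passes, a 60 s delay, eight test
    choice/reward passes, with unlabeled locomotion gaps; total ~152 s,
    matching the scale of real trials (~160 s).
    """
    sched = [(UNLABELED, 4.0)]
    for _ in range(4):
        sched += [("train_choice", 2.0), ("train_reward", 1.0), (UNLABELED, 4.0)]
    sched += [("delay", 60.0)]
    for _ in range(8):
        sched += [("test_choice", 2.0), ("test_reward", 1.0), (UNLABELED, 4.0)]
    sched += [(UNLABELED, 4.0)]
    return sched


@dataclass
class SynthParams:
    """Generator configuration; defaults define the standard study conditions."""

    n_units: int = 20
    n_trials: int = 10
    epoch_schedule: list | None = None  # (label, duration s); default maze trial
    latent_dim: int = 3
    attractor_centers: dict | None = None  # label -> latent fixed point
    convergence_rate: float = 2.0  # lambda, 1/s
    rotation_rate: float = 2.0  # omega, rad/s of the within-epoch orbit
    orbit_amplitude: float = 2.0  # radius of the circulating pull target
    orbit_directions: dict | None = None  # label -> +1/-1 circulation sense
    noise_sd: float = 0.25  # latent diffusion scale, 1/sqrt(s)
    loading: np.ndarray | None = None  # n_units x latent_dim rate gains
    baseline_rate: float = 10.0  # spikes/s
    rate_gain: float = 8.0  # scale of default loading entries, spikes/s
    center_scale: float = 2.0  # norm of default latent fixed points
    dt: float = 0.001  # simulation step, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_schedule is None:
            self.epoch_schedule = default_epoch_schedule()
        for label, dur in self.epoch_schedule:
            if dur <= 0:
                raise ValueError("epoch durations must be positive")
            if label != UNLABELED and label not in EPOCH_LABELS:
                raise ValueError(f"unknown epoch label {label!r}")
        if self.convergence_rate < 0:
            raise ValueError("convergence_rate must be >= 0")
        if self.attractor_centers is not None:
            for c in self.attractor_centers.values():
                if not np.all(np.isfinite(c)):
                    raise ValueError("non-finite attractor center")

    @property
    def trial_duration(self) -> float:
        return float(sum(d for _, d in self.epoch_schedule))


@dataclass
class SyntheticDataset:
    """Simulator output: spikes, latents, labels, and generation parameters."""

    spikes: list  # SpikeTrainSet per trial
    latents: list  # per trial: (n_steps x latent_dim) latent trajectory
    windows: list  # (label, start_s, end_s, trial_id) for labeled segments
    params: SynthParams

    def spike_frame(self) -> pd.DataFrame:
        """Long-format spike table (unit_id, time_s, trial_id)."""
        rows = []
        for st in self.spikes:
            for uid, times in st.units.items():
                rows.append(
                    pd.DataFrame(
                        {"unit_id": uid, "time_s": times, "trial_id": st.trial_id}
                    )
                )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["unit_id", "time_s", "trial_id"]
        )

    def event_frame(self) -> pd.DataFrame:
        """Explicit-window event table readable by preprocess.build_epoch_timeline."""
        return pd.DataFrame(
            [
                {"trial_id": t, "label_or_event": lab, "start_s": a, "end_s": b}
                for (lab, a, b, t) in self.windows
            ]
        )

    def write_csv(self, spike_path, event_path) -> None:
        self.spike_frame().to_csv(spike_path, index=False)
        self.event_frame().to_csv(event_path, index=False)


def _epoch_kind(label: str) -> str:
    if label.endswith("choice"):
        return "choice"
    if label.endswith("reward"):
        return "reward"
    return label


def _default_centers(params: SynthParams, rng: np.random.Generator) -> dict:
    """One fixed point per epoch *kind*: training and test epochs of the same
    kind share their center (they differ only in circulation direction)."""
    labels = [l for l in dict.fromkeys(l for l, _ in params.epoch_schedule) if l != UNLABELED]
    centers = {UNLABELED: np.zeros(params.latent_dim)}
    kind_centers: dict = {}
    for lab in labels:
        kind = _epoch_kind(lab)
        if kind not in kind_centers:
            v = rng.standard_normal(params.latent_dim)
            kind_centers[kind] = params.center_scale * v / np.linalg.norm(v)
        centers[lab] = kind_centers[kind]
    return centers


def _default_directions(labels) -> dict:
    out = {}
    for lab in labels:
        out[lab] = -1.0 if (lab.startswith("test") or lab.startswith("error")) else 1.0
    out[UNLABELED] = 1.0
    return out


def _default_loading(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    return (
        params.rate_gain
        / np.sqrt(params.latent_dim)
        * rng.standard_normal((params.n_units, params.latent_dim))
    )


def generate_dataset(params: SynthParams) -> SyntheticDataset:
    """Simulate spikes from the switching-OU latent model; fully seeded.

    The latent is integrated with the exact OU discretization (an AR(1)
    recursion evaluated by a linear filter), the rectified-linear rates are
    sampled at ``dt`` resolution, and spike counts per step are Poisson with
    a uniform jitter inside the step.
    """
    rng = np.random.default_rng(params.seed)
    centers = (
        {k: np.asarray(v, float) for k, v in params.attractor_centers.items()}
        if params.attractor_centers is not None
        else _default_centers(params, rng)
    )
    centers.setdefault(UNLABELED, np.zeros(params.latent_dim))
    loading = (
        np.asarray(params.loading, float)
        if params.loading is not None
        else _default_loading(params, rng)
    )

    dt = params.dt
    lam = params.convergence_rate
    a = np.exp(-lam * dt)
    if lam > 0:
        noise_step = params.noise_sd * np.sqrt((1 - a**2) / (2 * lam))
    else:
        noise_step = params.noise_sd * np.sqrt(dt)

    # per-step epoch label/center sequence, shared across trials
    steps_per_seg = [int(round(d / dt)) for _, d in params.epoch_schedule]
    n_steps = sum(steps_per_seg)
    seg_labels = np.concatenate(
        [
            np.full(k, lab, dtype=object)
            for (lab, _), k in zip(params.epoch_schedule, steps_per_seg)
        ]
    )
    base_center_seq = np.stack(
        [centers.get(lab, centers[UNLABELED]) for lab in seg_labels]
    )  # n_steps x latent_dim
    directions = params.orbit_directions or _default_directions(
        {lab for lab, _ in params.epoch_schedule}
    )
    orbit = (
        params.rotation_rate != 0
        and params.orbit_amplitude != 0
        and params.latent_dim >= 2
    )

    windows_one_trial = []
    t_cursor = 0.0
    for lab, d in params.epoch_schedule:
        if lab != UNLABELED:
            windows_one_trial.append((lab, t_cursor, t_cursor + d))
        t_cursor += d
    duration = t_cursor

    spikes, latents, windows = [], [], []
    for trial in range(params.n_trials):
        center_seq = base_center_seq
        if orbit:
            # circulating pull target: per-segment random initial phase keeps
            # the position marginal identical across circulation directions
            phase = np.empty(n_steps)
            pos = 0
            for (lab, _), k in zip(params.epoch_schedule, steps_per_seg):
                sense = directions.get(lab, 1.0)
                theta0 = rng.uniform(0, 2 * np.pi)
                phase[pos : pos + k] = theta0 + sense * params.rotation_rate * dt * np.arange(k)
                pos += k
            center_seq = base_center_seq.copy()
            center_seq[:, 0] += params.orbit_amplitude * np.cos(phase)
            center_seq[:, 1] += params.orbit_amplitude * np.sin(phase)
        eps = rng.standard_normal((n_steps, params.latent_dim))
        z0 = center_seq[0]
        z = np.empty((n_steps, params.latent_dim))
        for k in range(params.latent_dim):
            drive = (1 - a) * center_seq[:, k] + noise_step * eps[:, k]
            z[:, k], _ = lfilter([1.0], [1.0, -a], drive, zi=[a * z0[k]])
        rates = np.maximum(params.baseline_rate + z @ loading.T, 0.0)
        counts = rng.poisson(rates * dt)  # n_steps x n_units
        units = {}
        step_starts = dt * np.arange(n_steps)
        for u in range(params.n_units):
            c = counts[:, u]
            nz = np.flatnonzero(c)
            times = np.repeat(step_starts[nz], c[nz]) + dt * rng.random(int(c[nz].sum()))
            units[f"u{u:02d}"] = np.sort(np.minimum(times, duration))
        spikes.append(SpikeTrainSet(trial_id=trial, units=units, trial_span=(0.0, duration)))
        latents.append(z)
        windows.extend((lab, a_, b_, trial) for (lab, a_, b_) in windows_one_trial)

    return SyntheticDataset(spikes=spikes, latents=latents, windows=windows, params=params)


def make_null_variant(d: SyntheticDataset, mode: str) -> SyntheticDataset:
    """Matched null datasets for the bootstrap contrasts.

    ``single_center``: regenerate with every labeled epoch pulled toward the
    same (mean) fixed point and circulating in the same direction — no epoch
    structure, same autocorrelations.
    ``label_shuffle``: permute epoch labels over the labeled windows.
    ``time_invert``: reflect spike times within every labeled window (the
    binned-rate analog lives in :func:`msuaflow.resample.time_invert_epochs`).
    """
    params = d.params
    if mode == "single_center":
        rng = np.random.default_rng(params.seed)
        centers = (
            {k: np.asarray(v, float) for k, v in params.attractor_centers.items()}
            if params.attractor_centers is not None
            else _default_centers(params, rng)
        )
        labeled = [k for k in centers if k != UNLABELED]
        shared = np.mean([centers[k] for k in labeled], axis=0)
        new_centers = {k: (shared if k != UNLABELED else centers[k]) for k in centers}
        flat_dirs = {k: 1.0 for k in list(centers) + [UNLABELED]}
        return generate_dataset(
            replace(params, attractor_centers=new_centers, orbit_directions=flat_dirs)
        )
    if mode == "label_shuffle":
        rng = np.random.default_rng(params.seed + 1)
        labs = [w[0] for w in d.windows]
        perm = rng.permutation(len(labs))
        new_windows = [
            (labs[perm[i]], w[1], w[2], w[3]) for i, w in enumerate(d.windows)
        ]
        return SyntheticDataset(
            spikes=d.spikes, latents=d.latents, windows=new_windows, params=params
        )
    if mode == "time_invert":
        new_spikes = []
        for st in d.spikes:
            wins = [(a, b) for (lab, a, b, t) in d.windows if t == st.trial_id]
            units = {}
            for uid, times in st.units.items():
                t = times.copy()
                for a, b in wins:
                    inside = (t >= a) & (t < b)
                    t[inside] = a + b - t[inside]
                units[uid] = np.sort(t)
            new_spikes.append(SpikeTrainSet(st.trial_id, units, st.trial_span))
        return SyntheticDataset(
            spikes=new_spikes, latents=d.latents, windows=d.windows, params=params
        )
    raise ValueError(f"unknown null mode {mode!r}")
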