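"""Surrogate (bootstrap) datasets and nonparametric exceedance tests.

Surrogates randomize the relation between population vectors and epoch labels
while preserving temporal autocorrelations: epoch-block shuffles permute whole
within-epoch stretches of the vector time series under a fixed label timeline;
time inversion reverses bin order within each epoch, destroying causal
structure but keeping lengths and marginals; augmentation/decimation resample
vectors within epochs without altering the marginal distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

logger = logging.getLogger(__name__)


@dataclass
class SurrogateSpec:
    """Configuration of a surrogate ensemble."""

    mode: str  # epoch_block_shuffle | time_invert | augment | decimate
    n_replications: int = 100
    seed: int = 0
    factor: float = 1.0  # augmentation multiple or decimation fraction

    def __post_init__(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.mode == "decimate" and not (0 < self.factor <= 1):
            raise ValueError("decimation fraction must be in (0, 1]")


@dataclass
class BootstrapEnsemble:
    """Null distribution of a statistic plus the observed value."""

    statistics: np.ndarray
    observed: float
    p_value: float
    alternative: str
    n_failed: int = 0


def _blocks(labels: np.ndarray, trial_ids: np.ndarray | None) -> list:
    """Maximal runs of constant (trial, label): list of slices."""
    labels = np.asarray(labels)
    n = len(labels)
    if trial_ids is None:
        trial_ids = np.zeros(n)
    trial_ids = np.asarray(trial_ids)
    out = []
    start = 0
    for i in range(1, n + 1):
        if (
            i == n
            or labels[i] != labels[start]
            or trial_ids[i] != trial_ids[start]
        ):
            out.append(slice(start, i))
            start = i
    return out


def epoch_block_shuffle(
    values: np.ndarray,
    labels: np.ndarray,
    trial_ids=None,
    seed=None,
    length_tol: float = 0.10,
    chunk_length: int | None = None,
) -> np.ndarray:
    """Permute whole epoch blocks of the vector series; labels stay in place.

    The series is cut at epoch boundaries; block contents are permuted
    uniformly at random while the label timeline is untouched, so the
    vector-to-label assignment is randomized but within-block autocorrelations
    survive. Blocks are only exchanged with blocks of compatible length
    (within ``length_tol`` relative difference) so the fixed label timeline
    stays aligned with block contents.

    With ``chunk_length`` set, every epoch block is first subdivided into
    consecutive chunks of that length (autocorrelations then survive up to
    the chunk length — typically the shortest relevant epoch), and the
    equal-length chunks permute freely across the whole series. Without it,
    blocks of unique length (such as a single long delay period) can never
    move, which leaves part of the vector-label relation intact.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(values)
    blocks = _blocks(labels, trial_ids)
    if chunk_length is not None and chunk_length >= 1:
        pieces = []
        for b in blocks:
            start = b.start
            while start < b.stop:
                stop = min(start + chunk_length, b.stop)
                pieces.append(slice(start, stop))
                start = stop
        blocks = pieces
    if len(blocks) < 2:
        raise ValueError("need at least 2 labeled blocks to shuffle")

    lengths = np.array([b.stop - b.start for b in blocks])
    order = np.argsort(lengths, kind="stable")
    groups, current = [], [order[0]]
    for idx in order[1:]:
        if lengths[idx] <= lengths[current[0]] * (1 + length_tol):
            current.append(idx)
        else:
            groups.append(current)
            current = [idx]
    groups.append(current)

    assignment = np.arange(len(blocks))
    for g in groups:
        g = np.asarray(g)
        assignment[g] = g[rng.permutation(len(g))]

    out = np.empty_like(values)
    pos = 0
    for slot in range(len(blocks)):
        content = values[blocks[assignment[slot]]]
        out[pos : pos + len(content)] = content
        pos += len(content)
    return out


def time_invert_epochs(
    values: np.ndarray, labels: np.ndarray, trial_ids=None
) -> np.ndarray:
    """Reverse the bin order within every epoch block, all units together.

    Epoch lengths, labels and within-epoch marginals are preserved, but any
    causal (time-asymmetric) structure is destroyed. Applying it twice is the
    identity.
    """
    values = np.asarray(values)
    out = values.copy()
    for b in _blocks(labels, trial_ids):
        out[b] = values[b][::-1]
    return out


def augment_decimate(
    values: np.ndarray,
    labels: np.ndarray,
    spec: SurrogateSpec,
    ks_warn: float = 0.05,
):
    """Resample vectors within each epoch class to alter the sample size.

    Augmentation draws with replacement to ``factor`` times the original
    per-class count; decimation keeps a uniform random fraction. Returns
    ``(values, labels, ks_report)`` where the report holds the per-unit KS
    distance between original and resampled marginals (it should stay small:
    resampling must not alter the distributions).
    """
    if not (0.5 <= spec.factor <= 20):
        logger.warning("factor %.3g outside the customary [0.5, 20] range", spec.factor)
    rng = np.random.default_rng(spec.seed)
    values = np.asarray(values)
    labels = np.asarray(labels)
    keep_v, keep_l = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if spec.mode == "augment":
            n_new = int(round(spec.factor * len(idx)))
            take = rng.choice(idx, size=n_new, replace=True)
        elif spec.mode == "decimate":
            n_new = max(int(round(spec.factor * len(idx))), 1)
            take = rng.choice(idx, size=n_new, replace=False)
        else:
            raise ValueError(f"unknown mode {spec.mode!r}")
        keep_v.append(values[take])
        keep_l.append(labels[take])
    new_v = np.concatenate(keep_v, axis=0)
    new_l = np.concatenate(keep_l)
    ks = np.array(
        [ks_2samp(values[:, j], new_v[:, j]).statistic for j in range(values.shape[1])]
    )
    if (ks > ks_warn).any():
        logger.warning(
            "resampling shifted marginals: max per-unit KS distance %.3f", ks.max()
        )
    return new_v, new_l, ks


def bootstrap_test(
    statistic,
    original,
    surrogate_fn,
    n_replications: int = 100,
    seed=None,
    alternative: str = "less",
) -> BootstrapEnsemble:
    """One-sided exceedance test of a statistic against a surrogate null.

    ``statistic(dataset)`` maps a dataset to a scalar; ``surrogate_fn(dataset,
    rng)`` builds one surrogate replication. The p-value uses the add-one rule
    p = (1 + #extreme) / (n + 1), with "extreme" meaning surrogate <= observed
    for ``alternative='less'`` (the observed value is suspected LOW under the
    null) and >= for ``'greater'``. Replication seeds derive deterministically
    from ``seed``.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    rng = np.random.default_rng(seed)
    observed = float(statistic(original))
    stats, failed = [], 0
    for _ in range(n_replications):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        try:
            stats.append(float(statistic(surrogate_fn(original, child))))
        except Exception as exc:  # noqa: BLE001 - logged and counted
            failed += 1
            logger.warning("surrogate replication failed: %s", exc)
    if failed > 0.1 * n_replications:
        raise RuntimeError(
            f"{failed}/{n_replications} surrogate replications failed"
        )
    stats_arr = np.asarray(stats)
    if alternative == "less":
        extreme = int((stats_arr <= observed).sum())
    else:
        extreme = int((stats_arr >= observed).sum())
    p = (1 + extreme) / (len(stats_arr) + 1)
    return BootstrapEnsemble(
        statistics=stats_arr,
        observed=observed,
        p_value=float(p),
        alternative=alternative,
        n_failed=failed,
    )
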