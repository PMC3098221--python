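"""End-to-end analysis recipes built from the low-level modules.

These functions wire the stages together the way a full analysis runs them:
simulate (or load) spikes -> smoothed binned rates + epoch timeline ->
delay-coordinate embedding -> kernel discriminant / kernel-PCA statistics.
They are the engine behind the command-line interface and the built-in
validation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import discriminant, embed, geometry, preprocess, resample, synthdata
from .discriminant import SplitSpec
from .preprocess import UNLABELED


@dataclass
class PreparedData:
    """Binned rates, labels and delay-embedded vectors for one dataset."""

    rates: preprocess.RateMatrix
    timeline: preprocess.EpochTimeline
    dc: embed.DCMatrix

    @property
    def values(self) -> np.ndarray:
        return self.dc.values

    @property
    def labels(self) -> np.ndarray:
        return self.dc.labels

    @property
    def trial_ids(self) -> np.ndarray:
        return self.dc.trial_ids


def prepare(
    dataset: synthdata.SyntheticDataset,
    sigma: float = 0.2,
    bin_width: float = 0.2,
    max_lag_frac: float = 0.05,
    qc: bool = False,
) -> PreparedData:
    """Spikes -> QC -> rates -> timeline -> delay-coordinate matrix."""
    trains = dataset.spikes
    if qc:
        trains, _ = preprocess.qc_filter_units(trains)
    rates = preprocess.estimate_rates(trains, sigma=sigma, bin_width=bin_width)
    timeline = preprocess.build_epoch_timeline(dataset.windows, rates)
    delays = embed.select_delays(rates, timeline, max_lag_frac=max_lag_frac)
    dc = embed.build_dc_msua(rates, delays, timeline=timeline)
    return PreparedData(rates=rates, timeline=timeline, dc=dc)


def default_split(prep: PreparedData) -> SplitSpec:
    """First half of the trials as reference, second half as prediction."""
    trials = list(pd.unique(prep.trial_ids))
    half = len(trials) // 2
    if half < 1:
        raise ValueError("need at least 2 trials for a reference/prediction split")
    return SplitSpec(ref_trials=trials[:half], pred_trials=trials[half:])


# ---------------------------------------------------------------------------
# one-vs-rest epoch models: likelihoods and full-space decisions


def fit_epoch_models(
    values: np.ndarray,
    labels: np.ndarray,
    classes,
    O: int,
    eta: float = 0.05,
    max_per_class: int | None = None,
    rng: np.random.Generator | None = None,
    calibrate_frac: float = 0.0,
) -> dict:
    """One kernel-FDA model per epoch (epoch vs rest), on reference vectors.

    Returns ``{class: (model, train_rows)}`` where ``train_rows`` are the row
    indices of the training vectors (needed to build cross-kernels later).
    ``max_per_class`` caps the rest-class and the epoch class alike to bound
    the kernel size.

    With ``calibrate_frac`` > 0, the trailing fraction of each class's
    vectors is held out of the discriminant fit and used only to re-estimate
    the class Gaussians from its projections. In-sample projections shrink on
    heavily expanded spaces, so likelihood magnitudes evaluated on new data
    are only meaningful when the Gaussians are calibrated on vectors not used
    for the direction (both parts still come from the reference trials).
    """
    labels = np.asarray(labels)
    models = {}
    for c in classes:
        pos = np.flatnonzero(labels == c)
        neg = np.flatnonzero((labels != c) & (labels != UNLABELED))
        if max_per_class is not None:
            if rng is not None:
                if len(pos) > max_per_class:
                    pos = np.sort(rng.choice(pos, max_per_class, replace=False))
                if len(neg) > max_per_class:
                    neg = np.sort(rng.choice(neg, max_per_class, replace=False))
            else:
                pos, neg = pos[:max_per_class], neg[:max_per_class]
        if calibrate_frac > 0:
            n_pos_fit = max(int(round((1 - calibrate_frac) * len(pos))), 2)
            n_neg_fit = max(int(round((1 - calibrate_frac) * len(neg))), 2)
            cal = np.concatenate([pos[n_pos_fit:], neg[n_neg_fit:]])
            pos, neg = pos[:n_pos_fit], neg[:n_neg_fit]
        else:
            cal = None
        rows = np.concatenate([pos, neg])
        lab2 = np.where(labels[rows] == c, c, "rest").astype(object)
        K = embed.poly_kernel(values[rows], values[rows], O)
        model = discriminant.fit_kfda(K, lab2, eta=eta)
        if cal is not None and len(cal) >= 4:
            Kc = embed.poly_kernel(values[cal], values[rows], O)
            res = discriminant.classify(model, Kc)
            cal_lab = np.where(labels[cal] == c, c, "rest")
            stats = {}
            for name in model.classes:
                x = res.projections[cal_lab == name, 0]
                if len(x) >= 2 and np.std(x, ddof=1) > 0:
                    stats[name] = (float(np.mean(x)), float(np.std(x, ddof=1)))
                else:  # too few holdout vectors: keep in-sample stats
                    stats[name] = model.class_stats[name]
            model.class_stats = stats
        models[c] = (model, rows)
    return models


def epoch_likelihoods_and_decisions(
    models: dict,
    ref_values: np.ndarray,
    new_values: np.ndarray,
    new_labels: np.ndarray,
    O: int,
    z_clip: float | None = None,
) -> tuple:
    """Correct-class likelihoods and argmax epoch decisions for new vectors.

    For each epoch model, new vectors are projected on the frozen epoch-vs-
    rest axis; p(v(t)|C) is the epoch-class Gaussian likelihood. The decision
    at t is the epoch with the largest likelihood (equal priors), and the
    correct-class likelihood is the one of the true label. ``z_clip`` floors
    each Gaussian at its value ``z_clip`` SDs from the mean so that a few
    far-off-axis vectors cannot dominate averages of log-likelihoods.
    """
    from scipy.stats import norm

    classes = list(models)
    like = np.empty((len(new_values), len(classes)))
    post = np.empty((len(new_values), len(classes)))
    for k, c in enumerate(classes):
        model, rows = models[c]
        Kx = embed.poly_kernel(new_values, ref_values[rows], O)
        res = discriminant.classify(model, Kx)
        pos_col = list(model.classes).index(c)
        vals = res.likelihoods[:, pos_col]
        if z_clip is not None:
            _, sd = model.class_stats[c]
            vals = np.maximum(vals, norm.pdf(z_clip) / sd)
        like[:, k] = vals
        post[:, k] = res.posteriors[:, pos_col]
    # decisions compare the calibrated epoch-vs-rest posteriors, which are
    # dimensionless and hence commensurable across the per-epoch models
    decisions = np.asarray(classes, dtype=object)[np.argmax(post, axis=1)]
    new_labels = np.asarray(new_labels)
    correct = np.full(len(new_values), np.nan)
    for k, c in enumerate(classes):
        mask = new_labels == c
        correct[mask] = like[mask, k]
    return correct, decisions


def fit_pair_models(
    values: np.ndarray,
    labels: np.ndarray,
    classes,
    O: int,
    eta: float = 0.05,
    max_per_class: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """One pairwise kernel-FDA model per epoch pair, for voting decisions."""
    labels = np.asarray(labels)
    models = {}
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            c1, c2 = classes[i], classes[j]
            parts = []
            for c in (c1, c2):
                pos = np.flatnonzero(labels == c)
                if max_per_class is not None and len(pos) > max_per_class:
                    if rng is not None:
                        pos = np.sort(rng.choice(pos, max_per_class, replace=False))
                    else:
                        pos = pos[:max_per_class]
                parts.append(pos)
            rows = np.concatenate(parts)
            K = embed.poly_kernel(values[rows], values[rows], O)
            key = tuple(sorted((c1, c2), key=str))
            models[key] = (discriminant.fit_kfda(K, labels[rows], eta=eta), rows)
    return models


def pairwise_vote_decisions(
    pair_models: dict, ref_values: np.ndarray, new_values: np.ndarray, O: int
) -> np.ndarray:
    """Epoch decisions by majority vote of the pairwise Bayes classifiers.

    Each pairwise discriminant votes for one of its two epochs; the label
    with the most votes wins (ties resolved in favor of the class winning
    the direct pairwise comparison, then first in order).
    """
    classes = sorted({c for pair in pair_models for c in pair}, key=str)
    votes = np.zeros((len(new_values), len(classes)), dtype=int)
    direct = {}
    for (c1, c2), (model, rows) in pair_models.items():
        Kx = embed.poly_kernel(new_values, ref_values[rows], O)
        res = discriminant.classify(model, Kx)
        direct[(c1, c2)] = res.predicted_labels
        for c in (c1, c2):
            votes[:, classes.index(c)] += res.predicted_labels == c
    out = np.empty(len(new_values), dtype=object)
    top = votes.max(axis=1)
    for i in range(len(new_values)):
        winners = [classes[k] for k in np.flatnonzero(votes[i] == top[i])]
        if len(winners) == 1:
            out[i] = winners[0]
        else:
            pair = tuple(sorted(winners[:2], key=str))
            out[i] = direct[pair][i] if pair in direct else winners[0]
    return out


# ---------------------------------------------------------------------------
# validation experiments


def chance_level_se(
    seed: int,
    n_units: int = 20,
    n_per_class: int = 400,
    O: int = 5,
    eta: float = 0.05,
    mean_rate: float = 5.0,
    bin_width: float = 0.2,
) -> float:
    """Held-out SE on label-uninformative data; should sit at chance (0.5).

    Two classes of population rate vectors are drawn from one stationary
    Poisson ensemble (rates Poisson(mean_rate * bin_width) / bin_width), so
    the labels carry no information. A kernel-FDA classifier with equal
    priors is fitted on a random half and evaluated on the held-out half.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.poisson(mean_rate * bin_width, size=(n, n_units)) / bin_width
    y = np.array(["C1"] * n_per_class + ["C2"] * n_per_class, dtype=object)
    perm = rng.permutation(n)
    train, test = perm[: n // 2], perm[n // 2 :]
    K = embed.poly_kernel(X[train], X[train], O)
    model = discriminant.fit_kfda(K, y[train], eta=eta)
    Kx = embed.poly_kernel(X[test], X[train], O)
    res = discriminant.classify(model, Kx, true_labels=y[test])
    return float(res.se)


def sweep_statistic(
    values: np.ndarray,
    labels: np.ndarray,
    trial_ids: np.ndarray,
    split: SplitSpec,
    O: int,
    eta: float = 0.05,
    max_per_class: int | None = 120,
) -> float:
    """Mean forward SE_predic across epoch pairs at a single order."""
    table = discriminant.pairwise_epoch_sweep(
        values,
        labels,
        trial_ids,
        split,
        O_list=(O,),
        eta=eta,
        max_per_class=max_per_class,
        directions=("forward",),
    )
    return float(table["SE_predic"].mean())


def se_predic_bootstrap(
    prep: PreparedData,
    split: SplitSpec,
    O: int = 5,
    eta: float = 0.05,
    n_replications: int = 100,
    seed: int = 0,
    max_per_class: int | None = 120,
) -> resample.BootstrapEnsemble:
    """Compare mean SE_predic against the epoch-block-shuffle null.

    Each replication permutes epoch-length chunks of the vector series
    (labels fixed) independently within the reference and prediction trials,
    then reruns the cross-trial sweep; one-sided test that the original
    SE_predic is lower than under the null. Chunks are the length of the
    shortest epoch entering the sweep, so every replication preserves
    temporal autocorrelations up to that epoch length while fully
    randomizing the vector-to-label assignment.
    """
    values, labels, trial_ids = prep.values, prep.labels, prep.trial_ids
    eligible = [
        c
        for c in pd.unique(labels)
        if c != UNLABELED and c not in preprocess.REWARD_LABELS
    ]
    run_lengths = [
        sl.stop - sl.start
        for lab, sl in prep.timeline.block_runs(prep.rates.trial_ids)
        if lab in eligible
    ]
    chunk = int(min(run_lengths)) if run_lengths else None

    def stat(dataset):
        v, l, t = dataset
        return sweep_statistic(v, l, t, split, O, eta, max_per_class)

    def surrogate(dataset, rng):
        v, l, t = dataset
        out = v.copy()
        for trials in (split.ref_trials, split.pred_trials):
            mask = np.isin(t, trials)
            out[mask] = resample.epoch_block_shuffle(
                v[mask],
                l[mask],
                t[mask],
                seed=rng.integers(0, 2**31 - 1),
                chunk_length=chunk,
            )
        return out, l, t

    return resample.bootstrap_test(
        stat,
        (values, labels, trial_ids),
        surrogate,
        n_replications=n_replications,
        seed=seed,
        alternative="less",
    )


def convergence_slopes(
    prep: PreparedData,
    split: SplitSpec,
    O: int = 5,
    eta: float = 0.05,
    max_per_class: int = 150,
    n_bins: int = 20,
    seed: int = 0,
) -> dict:
    """Likelihood–velocity slope on prediction trials, original vs inverted.

    Fits epoch-vs-rest models on the reference trials, computes out-of-sample
    correct-class likelihoods on the prediction trials, and charts them
    against speeds in the 3-D kernel-PCA projection (basis frozen from the
    reference trials). The time-inverted surrogate reverses the rate series
    within epochs, is re-embedded, and its likelihoods are charted against
    the same empirical velocity field, so the contrast isolates the causal
    structure seen by the classifier. Returns both slope fits plus the
    paired slope comparison.
    """
    rng = np.random.default_rng(seed)
    in_ref = np.isin(prep.trial_ids, split.ref_trials)
    in_pred = np.isin(prep.trial_ids, split.pred_trials)
    labeled = prep.labels != UNLABELED
    classes = [c for c in pd.unique(prep.labels[in_ref & labeled])]

    ref_rows = np.flatnonzero(in_ref)
    models = fit_epoch_models(
        prep.values[ref_rows],
        prep.labels[ref_rows],
        classes,
        O,
        eta,
        max_per_class=max_per_class,
        rng=rng,
        calibrate_frac=0.3,
    )
    # 3-D kernel-PCA basis frozen from the reference trials. The velocity
    # field is measured once, from the original prediction series: the
    # time-inversion surrogate randomizes the assignment of population
    # vectors (and hence classifier likelihoods) to positions in the flow
    # while the empirically observed flow field itself is kept, so the
    # contrast isolates the causal structure seen by the classifier.
    basis = np.flatnonzero(in_ref & labeled)
    if len(basis) > 4 * max_per_class:
        basis = np.sort(rng.choice(basis, 4 * max_per_class, replace=False))
    proj = geometry.kernel_pca(
        embed.poly_kernel(prep.values[basis], prep.values[basis], O), d=3
    )
    rows = np.flatnonzero(in_pred & labeled)
    lab = prep.labels[rows]
    coords = proj.project(embed.poly_kernel(prep.values[rows], prep.values[basis], O))
    # velocities only between temporally adjacent bins of the same trial
    adjacent = (np.diff(prep.dc.row_index[rows]) == 1) & (
        prep.trial_ids[rows][1:] == prep.trial_ids[rows][:-1]
    )
    vel = np.diff(coords, axis=0)[adjacent]
    speeds = np.linalg.norm(vel, axis=1)
    # robust normalization: a single extreme jump must not compress the
    # whole speed axis into the lowest bins
    scale = np.quantile(speeds, 0.95)
    if scale > 0:
        speeds = np.clip(speeds / scale, 0.0, 1.0)
    pair_pos = np.flatnonzero(adjacent)
    # balance epochs in the curve so the long delay epoch does not swamp
    # the short choice/reward epochs carrying most of the transients
    keep_parts = []
    pair_lab = lab[pair_pos]
    for c in classes:
        pos_c = np.flatnonzero(pair_lab == c)
        if len(pos_c) > max_per_class:
            pos_c = np.sort(rng.choice(pos_c, max_per_class, replace=False))
        keep_parts.append(pos_c)
    keep = np.sort(np.concatenate(keep_parts))
    flow = geometry.FlowField(
        velocities=vel[keep],
        speeds=speeds[keep],
        index=pair_pos[keep],
        bin_width=prep.rates.bin_width,
    )

    def run(values_full: np.ndarray) -> geometry.SlopeFit:
        correct, _ = epoch_likelihoods_and_decisions(
            models, prep.values[ref_rows], values_full[rows], lab, O, z_clip=4.0
        )
        like = correct[pair_pos[keep]]
        ok = np.isfinite(like) & (like > 0)
        flow_ok = geometry.FlowField(
            velocities=flow.velocities[ok],
            speeds=flow.speeds[ok],
            index=flow.index[ok],
            bin_width=flow.bin_width,
        )
        return geometry.likelihood_velocity_curve(flow_ok, like[ok], n_bins=n_bins)

    fit_orig = run(prep.values)

    # time-inverted surrogate: invert the rate series within epochs, re-embed
    inv_rates = resample.time_invert_epochs(
        prep.rates.values, prep.timeline.labels, prep.rates.trial_ids
    )
    inv_matrix = preprocess.RateMatrix(
        values=inv_rates,
        bin_width=prep.rates.bin_width,
        sigma=prep.rates.sigma,
        bin_starts=prep.rates.bin_starts,
        unit_ids=prep.rates.unit_ids,
        trial_ids=prep.rates.trial_ids,
    )
    inv_dc = embed.build_dc_msua(
        inv_matrix, embed.DelaySpec(lags=prep.dc.lags), timeline=prep.timeline
    )
    fit_surr = run(inv_dc.values)

    comparison = geometry.compare_slopes(fit_orig, fit_surr)
    return {"original": fit_orig, "surrogate": fit_surr, "comparison": comparison}


def escape_experiment(
    prep: PreparedData,
    split: SplitSpec,
    O: int = 5,
    eta: float = 0.05,
    max_per_class: int = 150,
    k: int = 2,
    rho: float = 1.5,
    seed: int = 0,
) -> geometry.EscapeReport:
    """Escape fractions of prediction-trial trajectories from epoch states.

    Epoch membership of each bin comes from majority voting of the frozen
    pairwise full-space Bayes classifiers (reference-trial models);
    trajectory typing runs on these decisions and the trapping-region check
    uses the 3-D projection geometry.
    """
    rng = np.random.default_rng(seed)
    in_ref = np.isin(prep.trial_ids, split.ref_trials)
    in_pred = np.isin(prep.trial_ids, split.pred_trials)
    labeled = prep.labels != UNLABELED
    classes = [c for c in pd.unique(prep.labels[in_ref & labeled])]

    ref_rows = np.flatnonzero(in_ref)
    pair_models = fit_pair_models(
        prep.values[ref_rows],
        prep.labels[ref_rows],
        classes,
        O,
        eta,
        max_per_class=max_per_class,
        rng=rng,
    )
    pred_rows = np.flatnonzero(in_pred & labeled)
    X = prep.values[pred_rows]
    decisions = pairwise_vote_decisions(pair_models, prep.values[ref_rows], X, O)

    # geometry for the trapping check: shared kernel-PCA basis from reference
    ref_lab_rows = np.flatnonzero(in_ref & labeled)
    if len(ref_lab_rows) > 4 * max_per_class:
        ref_lab_rows = np.sort(
            rng.choice(ref_lab_rows, 4 * max_per_class, replace=False)
        )
    K_ref = embed.poly_kernel(prep.values[ref_lab_rows], prep.values[ref_lab_rows], O)
    proj = geometry.kernel_pca(K_ref, d=3)
    pred_coords = proj.project(
        embed.poly_kernel(X, prep.values[ref_lab_rows], O)
    )
    return geometry.escape_analysis(
        true_labels=prep.labels[pred_rows],
        predicted_labels=decisions,
        trial_ids=prep.trial_ids[pred_rows],
        projection=pred_coords,
        ref_coords=proj.coords,
        ref_labels=prep.labels[ref_lab_rows],
        k=k,
        rho=rho,
    )
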