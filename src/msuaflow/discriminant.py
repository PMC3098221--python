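"""Regularized kernel Fisher discriminant analysis and epoch classification.

The discriminant direction in the expanded space is found in dual form
(Mika-style): with a centered training kernel K (m x m) and class column
means M_c, the dual coefficients alpha solve

    (N + eta * mean(K_raw) * I) alpha = M_1 - M_2,

where N = sum_c K_c (I - 1/m_c) K_c^T is the within-class scatter operator in
dual coordinates, and the ridge is expressed as a fraction eta of the mean
raw kernel value. Projections x(t) = sum_j alpha_j k(v(t_j), v(t)) are
approximately Gaussian per class (they are sums of very many expanded-space
coordinates), so a Bayes-optimal classifier with equal priors is defined by
per-class Gaussians on the discriminant axis. The segregation error (SE) is
the fraction of misclassified population vectors; SE_predic is the same
quantity on prediction trials using the frozen reference-trial discriminant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, eigh, solve
from scipy.stats import norm
from sklearn.preprocessing import KernelCenterer

from .embed import KernelMatrix, poly_kernel
from .preprocess import REWARD_LABELS

logger = logging.getLogger(__name__)


@dataclass
class DiscriminantModel:
    """Fitted kernel-FDA solution for one epoch pair (or epoch set)."""

    alpha: np.ndarray  # m x n_components dual coefficients
    eta: float  # regularization as fraction of mean kernel value
    classes: tuple
    class_stats: dict  # class -> (mean, sd) of 1st-component projections
    priors: dict  # class -> prior probability
    centerer: KernelCenterer
    kernel_scale: float  # mean training kernel value; cross-kernels share it
    train_projections: np.ndarray  # m x n_components
    train_labels: np.ndarray
    train_index: np.ndarray | None = None  # time indices of training vectors

    @property
    def n_components(self) -> int:
        return self.alpha.shape[1]


@dataclass
class ClassifierResult:
    """Projections, likelihoods, posteriors and misclassification rate."""

    projections: np.ndarray
    likelihoods: np.ndarray  # n x n_classes, p(v(t)|C)
    posteriors: np.ndarray  # n x n_classes, P(C|v(t))
    predicted_labels: np.ndarray
    classes: tuple
    se: float | None = None  # fraction misclassified, if true labels known


@dataclass
class KLResult:
    """Discretized KL divergence between the two class Gaussians."""

    kl: float
    grid: np.ndarray
    symmetrized: bool = False


def _class_indices(labels: np.ndarray, classes) -> dict:
    labels = np.asarray(labels)
    return {c: np.flatnonzero(labels == c) for c in classes}


def fit_kfda(
    K: KernelMatrix,
    labels,
    eta: float = 0.05,
    n_components: int = 1,
    train_index: np.ndarray | None = None,
) -> DiscriminantModel:
    """Fit the regularized kernel Fisher discriminant in dual form.

    ``eta`` is the ridge penalty expressed as a fraction of the mean value of
    the raw kernel matrix. ``n_components`` is 1 for the pairwise classifier
    and typically 3 for visualization; with more than two classes the
    solution comes from the generalized symmetric eigenproblem
    M_b alpha = lambda (N + ridge I) alpha.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    labels = np.asarray(labels)
    Kv = np.asarray(K.values, dtype=float)
    m = Kv.shape[0]
    if Kv.shape[1] != m:
        raise ValueError("training kernel must be square")
    classes = tuple(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    idx = _class_indices(labels, classes)
    for c, ii in idx.items():
        if len(ii) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 vectors")

    # normalize the kernel scale so eta acts as a fraction of the mean kernel
    # value regardless of order O (raw O=5 kernels span ~15 decades)
    kscale = float(np.mean(Kv))
    if kscale <= 0 or not np.isfinite(kscale):
        raise ValueError("kernel matrix has non-positive or non-finite mean")
    Kn = Kv / kscale
    centerer = KernelCenterer().fit(Kn)
    Kc = centerer.transform(Kn.copy())

    # within-class scatter in dual coordinates
    N = np.zeros((m, m))
    for c, ii in idx.items():
        Ki = Kc[:, ii]
        N += Ki @ Ki.T - (Ki.sum(axis=1, keepdims=True) @ Ki.sum(axis=1, keepdims=True).T) / len(ii)
    N = 0.5 * (N + N.T)
    N[np.diag_indices_from(N)] += eta  # eta * mean(Kn) with mean(Kn) == 1

    Mc = {c: Kc[:, ii].mean(axis=1) for c, ii in idx.items()}
    try:
        if len(classes) == 2 and n_components == 1:
            alpha = solve(N, (Mc[classes[0]] - Mc[classes[1]]), assume_a="pos")
            alpha = alpha[:, None]
        else:
            mbar = np.mean([Mc[c] for c in classes], axis=0)
            Mb = np.zeros((m, m))
            for c in classes:
                d = (Mc[c] - mbar)[:, None]
                Mb += len(idx[c]) * (d @ d.T)
            w, v = eigh(Mb, N)
            order = np.argsort(w)[::-1]
            alpha = v[:, order[:n_components]]
    except LinAlgError as exc:
        raise LinAlgError(
            f"kernel-FDA system is singular (eta={eta}); increase eta"
        ) from exc

    proj = Kc @ alpha
    stats = {}
    for c, ii in idx.items():
        x = proj[ii, 0]
        sd = float(np.std(x, ddof=1))
        if sd <= 0 or not np.isfinite(sd):
            raise LinAlgError(
                f"degenerate class SD for {c!r}; increase eta or add data"
            )
        stats[c] = (float(np.mean(x)), sd)

    priors = {c: 1.0 / len(classes) for c in classes}
    return DiscriminantModel(
        alpha=alpha,
        eta=eta,
        classes=classes,
        class_stats=stats,
        priors=priors,
        centerer=centerer,
        kernel_scale=kscale,
        train_projections=proj,
        train_labels=labels,
        train_index=None if train_index is None else np.asarray(train_index),
    )


def gaussian_bayes(
    projections: np.ndarray, class_stats: dict, priors: dict, classes
) -> tuple:
    """Per-class Gaussian likelihoods, posteriors and MAP labels on the axis."""
    x = np.asarray(projections, dtype=float).ravel()
    like = np.stack(
        [norm.pdf(x, loc=class_stats[c][0], scale=class_stats[c][1]) for c in classes],
        axis=1,
    )
    pri = np.array([priors[c] for c in classes])
    joint = like * pri
    total = joint.sum(axis=1, keepdims=True)
    flat = total.ravel() == 0
    if flat.any():
        joint[flat] = pri  # both likelihoods underflow: fall back to priors
        total = joint.sum(axis=1, keepdims=True)
    post = joint / total
    ties = np.isclose(post.max(axis=1, keepdims=True), post).sum(axis=1) > 1
    if ties.any():
        logger.info("%d classification ties resolved to first class", int(ties.sum()))
    pred = np.asarray(classes, dtype=object)[np.argmax(post, axis=1)]
    return like, post, pred


def classify(
    model: DiscriminantModel, K_new: KernelMatrix, true_labels=None
) -> ClassifierResult:
    """Project new vectors on the frozen axis and apply the Bayes classifier.

    ``K_new`` must be the cross-kernel between the new vectors (rows) and the
    training vectors (columns).
    """
    Kv = np.asarray(K_new.values, dtype=float)
    if Kv.shape[1] != model.alpha.shape[0]:
        raise ValueError(
            "cross-kernel columns must index the training vectors "
            f"({Kv.shape[1]} != {model.alpha.shape[0]})"
        )
    Kc = model.centerer.transform(Kv / model.kernel_scale)
    proj = Kc @ model.alpha
    like, post, pred = gaussian_bayes(
        proj[:, 0], model.class_stats, model.priors, model.classes
    )
    se = None
    if true_labels is not None:
        true_labels = np.asarray(true_labels)
        se = float(np.mean(pred != true_labels))
    return ClassifierResult(
        projections=proj,
        likelihoods=like,
        posteriors=post,
        predicted_labels=pred,
        classes=model.classes,
        se=se,
    )


def se_predic(
    ref_model: DiscriminantModel,
    K_cross: KernelMatrix,
    pred_labels,
    pred_index: np.ndarray | None = None,
) -> ClassifierResult:
    """Out-of-sample SE on prediction vectors with the frozen reference model.

    Both the discriminant direction and the class Gaussians stay frozen from
    the reference fit. Reference and prediction time indices must be disjoint
    when both are known.
    """
    if pred_index is not None and ref_model.train_index is not None:
        if np.intersect1d(pred_index, ref_model.train_index).size:
            raise ValueError("sets must be disjoint")
    return classify(ref_model, K_cross, true_labels=pred_labels)


def kl_divergence(
    model: DiscriminantModel,
    n_cells: int = 1000,
    span_sd: float = 6.0,
    floor: float = 1e-12,
    symmetrized: bool = False,
) -> KLResult:
    """Discretized KL divergence between the two class Gaussians on the axis.

    The grid spans ±``span_sd`` pooled SDs around the grand mean of the class
    means, with ``n_cells`` cells; cell probabilities are floored at ``floor``
    and renormalized before summing p log(p/q).
    """
    if len(model.classes) != 2:
        raise ValueError("KL divergence is defined for the pairwise model")
    (m1, s1) = model.class_stats[model.classes[0]]
    (m2, s2) = model.class_stats[model.classes[1]]
    if s1 <= 0 or s2 <= 0:
        raise ValueError("degenerate class SD")
    pooled = np.sqrt((s1**2 + s2**2) / 2.0)
    center = 0.5 * (m1 + m2)
    edges = np.linspace(center - span_sd * pooled, center + span_sd * pooled, n_cells + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    w = edges[1] - edges[0]

    def cell_probs(mu, sd):
        p = norm.pdf(mid, mu, sd) * w
        p = np.maximum(p, floor)
        return p / p.sum()

    p = cell_probs(m1, s1)
    q = cell_probs(m2, s2)
    kl = float(np.sum(p * np.log(p / q)))
    if symmetrized:
        kl = 0.5 * (kl + float(np.sum(q * np.log(q / p))))
    return KLResult(kl=kl, grid=mid, symmetrized=symmetrized)


# ---------------------------------------------------------------------------
# pairwise sweep across epochs and expansion orders


@dataclass
class SplitSpec:
    """Reference / prediction trial assignment for cross-trial prediction."""

    ref_trials: list
    pred_trials: list

    def __post_init__(self) -> None:
        if set(self.ref_trials) & set(self.pred_trials):
            raise ValueError("sets must be disjoint")


def _take_first(idx: np.ndarray, n: int) -> np.ndarray:
    return idx[:n]


def pairwise_epoch_sweep(
    values: np.ndarray,
    labels: np.ndarray,
    trial_ids: np.ndarray,
    split: SplitSpec,
    O_list=(1, 2, 3, 5, 7),
    eta: float = 0.05,
    min_vectors: int = 10,
    exclude_rewards: bool = True,
    max_per_class: int | None = None,
    directions: tuple = ("forward", "backward"),
) -> pd.DataFrame:
    """SE, SE_predic and KL for every eligible epoch pair and expansion order.

    ``values`` are the base vectors (MSUA or delay-coordinate rows), with
    per-row ``labels`` and ``trial_ids``. For each pair of epochs and each
    order O, a kernel-FDA model is fitted on the reference trials and the
    frozen classifier is evaluated on the prediction trials (and vice versa
    for the backward direction). Per epoch, reference and prediction series
    are truncated to equal length; ``max_per_class`` optionally caps the
    number of vectors per class to bound compute.
    """
    labels = np.asarray(labels)
    trial_ids = np.asarray(trial_ids)
    in_ref = np.isin(trial_ids, split.ref_trials)
    in_pred = np.isin(trial_ids, split.pred_trials)

    eligible = []
    for c in pd.unique(labels):
        if c == "unlabeled":
            continue
        if exclude_rewards and c in REWARD_LABELS:
            continue
        n_r = int((in_ref & (labels == c)).sum())
        n_p = int((in_pred & (labels == c)).sum())
        if n_r >= min_vectors and n_p >= min_vectors:
            eligible.append(c)
    pairs = [
        (eligible[i], eligible[j])
        for i in range(len(eligible))
        for j in range(i + 1, len(eligible))
    ]
    if not pairs:
        raise ValueError("no eligible epoch pairs")

    rows = []
    for c1, c2 in pairs:
        sets = {}
        for name, mask in (("ref", in_ref), ("pred", in_pred)):
            sets[name] = {
                c: np.flatnonzero(mask & (labels == c)) for c in (c1, c2)
            }
        # truncate each epoch's series to equal length across the two sets
        for c in (c1, c2):
            n = min(len(sets["ref"][c]), len(sets["pred"][c]))
            if max_per_class is not None:
                n = min(n, max_per_class)
            sets["ref"][c] = _take_first(sets["ref"][c], n)
            sets["pred"][c] = _take_first(sets["pred"][c], n)

        for direction in directions:
            a, b = ("ref", "pred") if direction == "forward" else ("pred", "ref")
            fit_idx = np.concatenate([sets[a][c1], sets[a][c2]])
            eval_idx = np.concatenate([sets[b][c1], sets[b][c2]])
            fit_lab, eval_lab = labels[fit_idx], labels[eval_idx]
            for O in O_list:
                K = poly_kernel(values[fit_idx], values[fit_idx], O)
                model = fit_kfda(K, fit_lab, eta=eta, train_index=fit_idx)
                train_res = classify(model, K, true_labels=fit_lab)
                Kx = poly_kernel(values[eval_idx], values[fit_idx], O)
                pred_res = se_predic(model, Kx, eval_lab, pred_index=eval_idx)
                rows.append(
                    {
                        "epoch_pair": f"{c1}|{c2}",
                        "O": O,
                        "direction": direction,
                        "SE": train_res.se,
                        "SE_predic": pred_res.se,
                        "KL": kl_divergence(model).kl,
                        "n_ref": len(fit_idx),
                        "n_pred": len(eval_idx),
                    }
                )
    return pd.DataFrame(rows)
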