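"""Kernel PCA projections, flow fields, convergence and escape statistics,
and correlation-dimension diagnostics.

Velocities are measured in a low-dimensional (default 3-D) kernel-PCA
projection — finite differences in the full expanded space are unreliable —
while classifier decisions and likelihoods used for membership and
convergence statistics come from the full-space kernel discriminants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist
from sklearn.preprocessing import KernelCenterer

from .embed import KernelMatrix

logger = logging.getLogger(__name__)


@dataclass
class Projection3D:
    """Top-d kernel-PCA scores of the training vectors."""

    coords: np.ndarray  # m x d scores
    explained_variance: np.ndarray  # per-component score variance (lambda/m)
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # m x d
    centerer: KernelCenterer
    trial_ids: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def project(self, K_cross: KernelMatrix) -> np.ndarray:
        """Out-of-sample scores from a (new x train) cross-kernel."""
        Kc = self.centerer.transform(np.asarray(K_cross.values, float).copy())
        return Kc @ (self.eigenvectors / np.sqrt(self.eigenvalues))


@dataclass
class FlowField:
    """Forward-difference velocities of a projected trajectory."""

    velocities: np.ndarray  # (pairs) x d
    speeds: np.ndarray  # magnitudes, optionally normalized to [0, 1]
    index: np.ndarray  # row index (into the projection) of each pair's start
    bin_width: float = 1.0
    normalized: bool = True


@dataclass
class SlopeFit:
    """Log-linear fit of mean log-likelihood against binned speed."""

    n_bins: int
    bin_centers: np.ndarray
    bin_means: np.ndarray  # mean log-likelihood per nonempty bin
    slope: float
    intercept: float
    slope_se: float
    rms_error: float  # RMS fit residual relative to the geometric mean
    n_dropped_bins: int = 0


@dataclass
class EscapeReport:
    """Per-epoch counts of trajectory convergence types."""

    type_counts: dict  # epoch -> {"a": .., "b": .., "c": .., "escaped": ..}
    escape_fraction: dict  # epoch -> % escaped
    overall_escape_fraction: float  # %
    trapping_violations: float | None = None  # % of escaped leaving trap region


@dataclass
class CorrDimResult:
    """Correlation-sum dimension estimate with Theiler exclusion."""

    epsilons: np.ndarray
    correlation_sums: np.ndarray
    d2_slope: float
    takens_ml_d2: float
    b_min: int
    embedding_dim_needed: int
    scaling_region: tuple  # (eps_lo, eps_hi)
    reliable: bool = True


# ---------------------------------------------------------------------------
# kernel PCA


def kernel_pca(K: KernelMatrix, d: int = 3, trial_ids=None) -> Projection3D:
    """Double-center the kernel, eigendecompose, return the top-d scores.

    Scores are scaled so that the variance of component j equals
    eigenvalue_j / m, matching ordinary PCA on the expanded feature space
    (and exactly equal to it for order 1).
    """
    Kv = np.asarray(K.values, dtype=float)
    m = Kv.shape[0]
    if Kv.shape[1] != m or not np.allclose(Kv, Kv.T, atol=1e-8 * max(1.0, abs(Kv).max())):
        raise ValueError("kernel_pca needs a symmetric square kernel")
    centerer = KernelCenterer().fit(Kv)
    Kc = centerer.transform(Kv.copy())
    Kc = 0.5 * (Kc + Kc.T)
    w, v = eigh(Kc)
    w, v = w[::-1], v[:, ::-1]
    tol = max(m, 1) * np.finfo(float).eps * max(w.max(), 0.0)
    rank = int((w > tol).sum())
    if d > rank:
        logger.warning("requested %d components but rank is %d; truncating", d, rank)
        d = rank
    w, v = w[:d], v[:, :d]
    coords = v * np.sqrt(w)
    return Projection3D(
        coords=coords,
        explained_variance=w / m,
        eigenvalues=w,
        eigenvectors=v,
        centerer=centerer,
        trial_ids=None if trial_ids is None else np.asarray(trial_ids),
    )


# ---------------------------------------------------------------------------
# flow field and convergence


def velocity_field(
    coords: np.ndarray,
    trial_ids=None,
    bin_width: float = 1.0,
    normalize: bool = True,
) -> FlowField:
    """Forward differences of consecutive points, excluding cross-trial pairs.

    ``coords`` may be a Projection3D or a plain (T x d) array. Speeds are
    vector magnitudes, normalized to [0, 1] across all pairs by default.
    """
    if isinstance(coords, Projection3D):
        if trial_ids is None:
            trial_ids = coords.trial_ids
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return FlowField(
            velocities=np.empty((0, coords.shape[1] if coords.ndim == 2 else 1)),
            speeds=np.empty(0),
            index=np.empty(0, dtype=int),
            bin_width=bin_width,
            normalized=normalize,
        )
    vel = np.diff(coords, axis=0)
    idx = np.arange(n - 1)
    if trial_ids is not None:
        trial_ids = np.asarray(trial_ids)
        keep = trial_ids[1:] == trial_ids[:-1]
        vel, idx = vel[keep], idx[keep]
    speeds = np.linalg.norm(vel, axis=1)
    if normalize and speeds.size and speeds.max() > 0:
        speeds = speeds / speeds.max()
    return FlowField(
        velocities=vel, speeds=speeds, index=idx, bin_width=bin_width,
        normalized=normalize,
    )


def likelihood_velocity_curve(
    flow: FlowField, likelihoods: np.ndarray, n_bins: int = 20
) -> SlopeFit:
    """Mean log-likelihood of correct classification as a function of speed.

    Speeds are split into ``n_bins`` equal-width bins over their range; an
    ordinary least-squares line through (bin center, mean log-likelihood)
    gives the convergence slope b. ``likelihoods`` must be aligned with
    ``flow.index`` (the likelihood of the vector at each pair's start).
    Empty bins are dropped (logged); fewer than 5 nonempty bins is an error.
    A negative slope means fast-moving states are unlikely to be classified
    correctly, i.e. the flow decelerates near the epoch states.
    """
    like = np.asarray(likelihoods, dtype=float)
    if like.shape[0] != flow.speeds.shape[0]:
        raise ValueError("likelihoods must align with the flow field pairs")
    if (like <= 0).any():
        raise ValueError("likelihoods must be positive to take logs")
    s = flow.speeds
    if flow.normalized:
        lo, hi = 0.0, 1.0  # fixed grid: fits on different data share bins
    else:
        lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        raise ValueError("speeds are constant; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    dropped = 0
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            dropped += 1
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(float(np.mean(np.log(like[mask]))))
    if len(centers) < 5:
        raise ValueError("fewer than 5 nonempty speed bins")
    if dropped:
        logger.info("%d empty speed bins dropped from slope fit", dropped)
    x = np.asarray(centers)
    y = np.asarray(means)
    X = np.stack([np.ones_like(x), x], axis=1)
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    dof = max(len(x) - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    slope_se = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.inf
    # residuals in log space are relative deviations from the geometric mean
    rms = float(np.sqrt(np.mean(resid**2)))
    return SlopeFit(
        n_bins=n_bins,
        bin_centers=x,
        bin_means=y,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=slope_se,
        rms_error=rms,
        n_dropped_bins=dropped,
    )


def compare_slopes(fit_a: SlopeFit, fit_b: SlopeFit) -> dict:
    """Paired comparison of two slope fits across common speed bins.

    Regresses the per-bin difference of mean log-likelihoods on the bin
    centers; the t statistic of that regression's slope (df = n_bins - 2)
    tests whether the two convergence slopes differ.
    """
    common_a = {c: v for c, v in zip(fit_a.bin_centers, fit_a.bin_means)}
    common_b = {c: v for c, v in zip(fit_b.bin_centers, fit_b.bin_means)}
    xs = sorted(set(common_a) & set(common_b))
    if len(xs) < 5:
        raise ValueError("fewer than 5 common bins for slope comparison")
    x = np.asarray(xs)
    d = np.asarray([common_a[c] - common_b[c] for c in xs])
    X = np.stack([np.ones_like(x), x], axis=1)
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ beta
    dof = len(x) - 2
    s2 = float(resid @ resid) / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    se = np.sqrt(s2 / sxx)
    t_stat = float(beta[1] / se) if se > 0 else np.inf
    p_two = 2.0 * float(t_dist.sf(abs(t_stat), dof))
    return {
        "slope_diff": float(beta[1]),
        "t": t_stat,
        "p": p_two,
        "df": dof,
        "n_bins": len(xs),
    }


# ---------------------------------------------------------------------------
# escape trajectories


def _fill_short_gaps(member: np.ndarray, k: int) -> np.ndarray:
    """Treat non-member stretches shorter than k bins as membership noise."""
    out = member.copy()
    n = len(member)
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            if j - i < k:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _classify_trajectory(member: np.ndarray, k: int) -> str:
    eff = _fill_short_gaps(np.asarray(member, bool), k)
    if not eff[-1]:
        return "escaped"
    if eff.all():
        return "a"
    first_true = int(np.argmax(eff))
    if first_true > 0 and eff[first_true:].all():
        return "c"
    return "b"


def escape_analysis(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    trial_ids: np.ndarray,
    projection: np.ndarray | None = None,
    ref_coords: np.ndarray | None = None,
    ref_labels: np.ndarray | None = None,
    k: int = 2,
    rho: float = 1.5,
    skip_labels: tuple = ("unlabeled",),
) -> EscapeReport:
    """Type every within-epoch trajectory and count escapes.

    A trajectory is a maximal run of consecutive bins (within one trial)
    sharing the same true epoch label; bin t is a member of the epoch state
    when the full-space classifier assigns that label. Types: "a" confined,
    "b" departs (>= k consecutive non-member bins) but re-enters before the
    run ends, "c" converges from outside and stays, "escaped" departs without
    re-entering. Short non-member blips (< k bins) count as membership noise.

    If ``projection`` (coords of the analyzed bins), ``ref_coords`` and
    ``ref_labels`` are given, an escaped trajectory additionally violates the
    trapping region when any of its points is farther from the epoch's
    reference centroid than ``rho`` times the reference set's maximum member
    distance.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    trial_ids = np.asarray(trial_ids)

    centroids, radii = {}, {}
    if projection is not None and ref_coords is not None and ref_labels is not None:
        ref_labels = np.asarray(ref_labels)
        for c in np.unique(ref_labels):
            pts = np.asarray(ref_coords)[ref_labels == c]
            if len(pts):
                ctr = pts.mean(axis=0)
                centroids[c] = ctr
                radii[c] = float(np.linalg.norm(pts - ctr, axis=1).max())

    counts: dict = {}
    violations = 0
    n_escaped = 0
    n = len(true_labels)
    start = 0
    for i in range(1, n + 1):
        boundary = (
            i == n
            or true_labels[i] != true_labels[start]
            or trial_ids[i] != trial_ids[start]
        )
        if not boundary:
            continue
        label = true_labels[start]
        if label not in skip_labels:
            member = predicted_labels[start:i] == label
            ttype = _classify_trajectory(member, k)
            counts.setdefault(label, {"a": 0, "b": 0, "c": 0, "escaped": 0})
            counts[label][ttype] += 1
            if ttype == "escaped":
                n_escaped += 1
                if label in centroids and projection is not None:
                    pts = np.asarray(projection)[start:i]
                    dist = np.linalg.norm(pts - centroids[label], axis=1)
                    if (dist > rho * radii[label]).any():
                        violations += 1
        start = i

    if not counts:
        raise ValueError("no labeled trajectories found")
    esc_frac = {}
    for c, tc in counts.items():
        total = sum(tc.values())
        if total == 0:
            logger.warning("epoch %r has no trajectories; skipped", c)
            continue
        esc_frac[c] = 100.0 * tc["escaped"] / total
    grand_total = sum(sum(tc.values()) for tc in counts.values())
    overall = 100.0 * n_escaped / grand_total
    trapping = 100.0 * violations / n_escaped if (n_escaped and centroids) else None
    return EscapeReport(
        type_counts=counts,
        escape_fraction=esc_frac,
        overall_escape_fraction=overall,
        trapping_violations=trapping,
    )


# ---------------------------------------------------------------------------
# correlation dimension


def space_time_separation(
    points: np.ndarray,
    max_dt: int = 50,
    n_eps: int = 12,
    tol: float = 0.05,
) -> int:
    """Smallest temporal exclusion beyond which S(eps) is stable within tol.

    Computes correlation sums restricted to pairs at least Delta samples apart
    for Delta = 1..max_dt and returns the smallest Delta from which on the
    relative variation of S(eps) (against the largest-separation reference)
    stays below ``tol`` for all probed eps.
    """
    pts = np.asarray(points, dtype=float)
    m = len(pts)
    d = pdist(pts)
    ii, jj = np.triu_indices(m, k=1)
    dt = jj - ii
    pos = d[d > 0]
    if pos.size == 0:
        return 0
    eps = np.quantile(pos, np.linspace(0.05, 0.95, n_eps))
    max_dt = min(max_dt, m - 2)
    deltas = np.arange(1, max_dt + 1)
    S = np.empty((len(deltas), len(eps)))
    for k, delta in enumerate(deltas):
        sel = dt >= delta
        if sel.sum() < 10:
            S[k:] = S[k - 1] if k else 1.0
            break
        dd = d[sel]
        S[k] = np.searchsorted(np.sort(dd), eps, side="left") / len(dd)
    ref = S[-1]
    ref_safe = np.where(ref > 0, ref, 1.0)
    for k in range(len(deltas)):
        dev = np.abs(S[k:] - ref) / ref_safe
        if dev.max() < tol:
            return int(deltas[k])
    return int(deltas[-1])


def correlation_dimension(
    points: np.ndarray,
    theiler_window: int | None = None,
    n_eps: int = 40,
    min_decade: float = 0.5,
) -> CorrDimResult:
    """Grassberger–Procaccia correlation dimension with Theiler exclusion.

    S(eps) is the fraction of point pairs within eps, excluding pairs closer
    than ``theiler_window`` samples in time (chosen by
    :func:`space_time_separation` when not given). d2 is the slope of
    log S vs log eps over the longest contiguous window spanning at least
    ``min_decade`` decades that maximizes the linear-fit R^2; the Takens
    maximum-likelihood estimator over distances below the scaling region's
    upper edge serves as a cross-check. The minimum embedding dimension for a
    faithful reconstruction is 2*d2 + 1 (rounded up).
    """
    if isinstance(points, Projection3D):
        points = points.coords
    pts = np.asarray(points, dtype=float)
    m = len(pts)
    if m < 200:
        raise ValueError("need at least 200 points")
    if theiler_window is None:
        theiler_window = space_time_separation(pts)
    d = pdist(pts)
    ii, jj = np.triu_indices(m, k=1)
    keep = (jj - ii) >= max(theiler_window, 1)
    d = d[keep]
    d = d[d > 0]
    if d.size < 100:
        raise ValueError("too few admissible pairs after temporal exclusion")
    d_sorted = np.sort(d)
    eps = np.logspace(
        np.log10(d_sorted[max(int(0.001 * len(d_sorted)), 1)]),
        np.log10(d_sorted[-1]),
        n_eps,
    )
    S = np.searchsorted(d_sorted, eps, side="right") / len(d_sorted)

    ok = S > 0
    le, ls = np.log10(eps[ok]), np.log10(S[ok])
    best = None  # (r2_rounded, length, slope, (lo, hi))
    for a in range(len(le)):
        for b in range(a + 4, len(le)):
            if le[b] - le[a] < min_decade:
                continue
            x, y = le[a : b + 1], ls[a : b + 1]
            beta = np.polyfit(x, y, 1)
            fitted = np.polyval(beta, x)
            ss_res = float(((y - fitted) ** 2).sum())
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            cand = (round(r2, 4), b - a, float(beta[0]), (10 ** le[a], 10 ** le[b]))
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        return CorrDimResult(
            epsilons=eps,
            correlation_sums=S,
            d2_slope=np.nan,
            takens_ml_d2=np.nan,
            b_min=theiler_window,
            embedding_dim_needed=0,
            scaling_region=(np.nan, np.nan),
            reliable=False,
        )
    r2, _, slope, (eps_lo, eps_hi) = best
    inside = d_sorted[d_sorted <= eps_hi]
    takens = float(-len(inside) / np.sum(np.log(inside / eps_hi)))
    emb = int(np.ceil(2 * slope + 1))
    return CorrDimResult(
        epsilons=eps,
        correlation_sums=S,
        d2_slope=slope,
        takens_ml_d2=takens,
        b_min=int(theiler_window),
        embedding_dim_needed=emb,
        scaling_region=(eps_lo, eps_hi),
        reliable=bool(r2 > 0.98),
    )
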