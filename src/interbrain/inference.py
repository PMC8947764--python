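"""Analyses applied identically to recorded and simulated sessions.

Surrogate construction (correlation- and variance-preserving, timescale-
altering), behavior regression, rotation scans of inter-variable
correlation, coordinated-epoch removal, cross-brain behavior
discriminability (ROC), and difference-subspace statistics for group
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ActivityTimeSeries, BehaviorSequence
from .decomposition import (
    decompose_pair,
    interbrain_correlation,
    rotate_activity,
    spectral_summary,
)
from .neural_dynamics import moving_average

__all__ = [
    "SurrogateSession",
    "DifferenceSubspaceStats",
    "generate_surrogate",
    "regress_out_behavior",
    "correlation_vs_rotation",
    "remove_coordinated_epochs",
    "behavior_discrimination_auc",
    "encoding_roc",
    "difference_subspace_stats",
]


@dataclass
class SurrogateSession:
    """Surrogate dyad preserving correlation and component variances."""

    activity: ActivityTimeSeries
    original_correlation: float
    original_var_mean: float
    original_var_diff: float


def generate_surrogate(
    activity: ActivityTimeSeries,
    smoothing_window_s: float = 1000.0,
    seed: int | np.random.Generator = 0,
    max_retries: int = 10,
) -> SurrogateSession:
    """Replace the difference component with a slow surrogate.

    Keeps the original mean component and builds a surrogate difference
    component SD from uniform noise smoothed with a moving-average filter
    (default window 1000 s), orthogonalized against the mean component and
    recombined so that the surrogate has exactly the original inter-brain
    correlation, mean-component variance, and difference-component
    variance — while its timescales are set by the smoothing, not by the
    data. Construction: with hatted vectors time-mean-subtracted,

        R_hat   = mean-subtracted smoothed noise
        R_orth  = R_hat - [(R_hat . M_hat) / (M_hat . M_hat)] M_hat
        S'_D    = cot(angle(M_hat, D_hat)) * M_hat/|M_hat| + R_orth/|R_orth|
        S_D     = (|D_hat| / |S'_D|) S'_D + time-mean of the original diff
        S1, S2  = AM + SD, AM - SD
    """
    if activity.n_subjects != 2:
        raise ValueError("surrogate construction requires exactly 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pair = decompose_pair(activity)
    m_hat = pair.mean - pair.mean.mean()
    d_hat = pair.diff - pair.diff.mean()
    nm = np.linalg.norm(m_hat)
    nd = np.linalg.norm(d_hat)
    if nm == 0 or nd == 0:
        raise ValueError("constant mean or difference component")
    cos_angle = float(m_hat @ d_hat) / (nm * nd)
    if abs(cos_angle) >= 1.0 - 1e-12:
        raise ValueError(
            "mean and difference components are collinear; the surrogate "
            "construction is undefined (try a different seed or session)"
        )
    cot = cos_angle / np.sqrt(1.0 - cos_angle**2)
    window_bins = max(1, int(round(smoothing_window_s / activity.dt)))
    r_orth = None
    for _ in range(max_retries):
        r = moving_average(rng.uniform(0.0, 1.0, activity.n_bins), window_bins)
        r_hat = r - r.mean()
        cand = r_hat - (r_hat @ m_hat) / (m_hat @ m_hat) * m_hat
        if np.linalg.norm(cand) > 1e-12:
            r_orth = cand
            break
    if r_orth is None:
        raise RuntimeError("smoothed noise kept collapsing onto the mean component")
    s_prime = cot * m_hat / nm + r_orth / np.linalg.norm(r_orth)
    s_hat = (nd / np.linalg.norm(s_prime)) * s_prime
    sd = s_hat + pair.diff.mean()
    s1 = pair.mean + sd
    s2 = pair.mean - sd
    surrogate = ActivityTimeSeries(
        times=activity.times.copy(),
        values=np.vstack([s1, s2]),
        subject_ids=tuple(f"{sid}_surrogate" for sid in activity.subject_ids),
    )
    return SurrogateSession(
        activity=surrogate,
        original_correlation=interbrain_correlation(*activity.values),
        original_var_mean=float(np.var(pair.mean)),
        original_var_diff=float(np.var(pair.diff)),
    )


def _behavior_design(behaviors: BehaviorSequence, subjects: str | int = "both") -> np.ndarray:
    """Indicator design matrix (n_bins x n_predictors), plus intercept.

    One binary column per (subject, behavior) over the requested subjects;
    only behaviors that actually occur contribute columns.
    """
    if subjects == "both":
        rows = range(behaviors.n_subjects)
    else:
        rows = [int(subjects)]
    cols = [np.ones(behaviors.n_bins)]
    for i in rows:
        for name in behaviors.vocabulary.names:
            col = (behaviors.labels[i] == name).astype(float)
            if col.any():
                cols.append(col)
    return np.column_stack(cols)


def regress_out_behavior(
    activity_values: np.ndarray,
    behaviors: BehaviorSequence,
    subjects: str | int = "both",
) -> np.ndarray:
    """Residual of one activity series after regressing out behavior.

    Ordinary least squares of the series on the binary behavior time-course
    indicators (plus intercept); the indicator set spans both subjects by
    default, or one subject when ``subjects`` is an index. Minimum-norm
    solution under rank deficiency (indicators of one subject sum to the
    intercept), so the residual — the only consumed output — is unique.
    """
    y = np.asarray(activity_values, float)
    if y.ndim != 1 or y.size != behaviors.n_bins:
        raise ValueError("activity series must be 1-D on the behavior grid")
    x = _behavior_design(behaviors, subjects)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def correlation_vs_rotation(
    activity: ActivityTimeSeries,
    behaviors: BehaviorSequence | None = None,
    angles_deg: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlation between rotated activity variables over a grid of angles.

    For each angle, rotates the basis and correlates the two rotated
    variables; with behaviors given, also correlates the residuals after
    regressing out both subjects' behavior indicators from each rotated
    variable. A rotated variable that is numerically constant at some angle
    yields NaN at that point (flagged, not fatal).
    """
    if angles_deg is None:
        angles_deg = np.arange(0.0, 91.0, 5.0)
    rows = []
    for angle in np.asarray(angles_deg, float):
        rot = rotate_activity(activity, angle)
        v1, v2 = rot.values
        try:
            raw = interbrain_correlation(v1, v2)
        except ValueError:
            raw = np.nan
        reg = np.nan
        if behaviors is not None:
            r1 = regress_out_behavior(v1, behaviors)
            r2 = regress_out_behavior(v2, behaviors)
            try:
                reg = interbrain_correlation(r1, r2)
            except ValueError:
                reg = np.nan
        rows.append({"angle_deg": float(angle), "correlation_raw": raw,
                     "correlation_regressed": reg})
    return pd.DataFrame(rows)


def remove_coordinated_epochs(
    activity: ActivityTimeSeries, behaviors: BehaviorSequence
) -> tuple[np.ndarray, float, int]:
    """Drop bins where both subjects carry the same behavior label.

    Returns (kept activity values of shape (2, n_kept), correlation over the
    concatenated remainder, number of kept bins). Idempotent: the kept bins
    contain no coordinated epochs.
    """
    if activity.n_subjects != 2 or behaviors.n_subjects != 2:
        raise ValueError("requires a 2-subject session")
    if activity.n_bins != behaviors.n_bins:
        raise ValueError("activity and behavior grids do not match")
    keep = behaviors.labels[0] != behaviors.labels[1]
    kept = activity.values[:, keep]
    if kept.shape[1] < 3:
        raise ValueError(
            "fewer than 3 bins remain after removing coordinated behavior"
        )
    corr = interbrain_correlation(kept[0], kept[1])
    return kept, corr, int(kept.shape[1])


def behavior_discrimination_auc(
    observer_residuals: np.ndarray,
    other_behavior: np.ndarray,
    pair: tuple[str, str],
    min_count: int = 5,
) -> tuple[float, int, int]:
    """Rank-based ROC area for one behavior pair of the other subject.

    Compares the conditional distributions of the observer's residual
    activity during the other subject's two behaviors; ties count half
    (Mann-Whitney convention). Classes are assigned so the area is >= 0.5.
    Returns (auc, n_a, n_b).
    """
    residuals = np.asarray(observer_residuals, float)
    labels = np.asarray(other_behavior, dtype=object)
    a, b = pair
    xa = residuals[labels == a]
    xb = residuals[labels == b]
    if xa.size < min_count or xb.size < min_count:
        raise ValueError(
            f"behaviors {pair} need >= {min_count} bins each "
            f"(got {xa.size}, {xb.size})"
        )
    ranks = rankdata(np.concatenate([xa, xb]))
    u = ranks[: xa.size].sum() - xa.size * (xa.size + 1) / 2.0
    auc = u / (xa.size * xb.size)
    return float(max(auc, 1.0 - auc)), int(xa.size), int(xb.size)


def encoding_roc(
    activity: ActivityTimeSeries,
    behaviors: BehaviorSequence,
    min_count: int = 5,
) -> pd.DataFrame:
    """Cross-brain behavior discriminability table for a dyadic session.

    For each observer, the observer's own behavior is first regressed out of
    its activity; the residuals are then scored against every pair of
    behaviors that the other subject expresses at least ``min_count`` times.
    Returns columns (observer, behaver, behavior_a, behavior_b, auc,
    n_a, n_b).
    """
    if activity.n_subjects != 2:
        raise ValueError("encoding analysis requires a 2-subject session")
    rows = []
    for obs in (0, 1):
        other = 1 - obs
        resid = regress_out_behavior(activity.values[obs], behaviors, subjects=obs)
        labels = behaviors.labels[other]
        present = [
            name for name in behaviors.vocabulary.names
            if int((labels == name).sum()) >= min_count
        ]
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                auc, na, nb = behavior_discrimination_auc(
                    resid, labels, (a, b), min_count=min_count
                )
                rows.append({
                    "observer": activity.subject_ids[obs],
                    "behaver": activity.subject_ids[other],
                    "behavior_a": a, "behavior_b": b,
                    "auc": auc, "n_a": na, "n_b": nb,
                })
    return pd.DataFrame(rows)


@dataclass
class DifferenceSubspaceStats:
    """Mean-direction vs difference-subspace summaries of a group session.

    The mean direction uses the unit-norm all-ones projection — the same
    orthonormal convention as the random difference directions — so
    variances are directly comparable; ``mean_series`` additionally exposes
    the plain across-subject average for plotting (the two differ by a
    sqrt(n) scale, immaterial to centroids and correlations).
    """

    mean_variance: float
    mean_centroid_hz: float
    diff_variance_avg: float
    diff_centroid_avg_hz: float
    pairwise_correlations: np.ndarray
    mean_vs_diff_correlations: np.ndarray
    mean_series: np.ndarray = field(repr=False)


def _random_difference_directions(
    n: int, n_directions: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit vectors uniform on the sphere of the all-ones-orthogonal subspace."""
    ones = np.ones(n) / np.sqrt(n)
    v = rng.standard_normal((n_directions, n))
    v -= np.outer(v @ ones, ones)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero draw is measure-zero; guard anyway
    norms[norms == 0] = 1.0
    return v / norms


def difference_subspace_stats(
    activity: ActivityTimeSeries,
    n_directions: int = 1000,
    seed: int | np.random.Generator = 0,
) -> DifferenceSubspaceStats:
    """Mean-component vs difference-subspace statistics for n >= 3 subjects.

    The difference subspace is the (n-1)-dimensional orthogonal complement
    of the all-ones direction. Its average variance is the total variance of
    the orthonormal subspace projections divided by n-1 (equivalently, the
    total variance of the across-subject-mean-removed activity / (n-1));
    its average centroid and its correlations with the mean component are
    averaged over ``n_directions`` random unit directions in the subspace.
    """
    n = activity.n_subjects
    if n < 3:
        raise ValueError("difference_subspace_stats requires n >= 3 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = activity.values
    dt = activity.dt
    ones = np.ones(n) / np.sqrt(n)
    mean_proj = ones @ values  # orthonormal mean-direction coordinate
    mean_summary = spectral_summary(mean_proj, dt)
    total_var = float(np.var(values, axis=1).sum())
    diff_var_avg = (total_var - mean_summary.variance) / (n - 1)

    dirs = _random_difference_directions(n, n_directions, rng)
    projections = dirs @ values
    centroids = np.empty(n_directions)
    mean_corrs = np.empty(n_directions)
    for i in range(n_directions):
        centroids[i] = spectral_summary(projections[i], dt).centroid_hz
        mean_corrs[i] = interbrain_correlation(mean_proj, projections[i])

    pair_corrs = np.array([
        interbrain_correlation(values[i], values[j])
        for i in range(n) for j in range(i + 1, n)
    ])
    return DifferenceSubspaceStats(
        mean_variance=mean_summary.variance,
        mean_centroid_hz=mean_summary.centroid_hz,
        diff_variance_avg=diff_var_avg,
        diff_centroid_avg_hz=float(centroids.mean()),
        pairwise_correlations=pair_corrs,
        mean_vs_diff_correlations=mean_corrs,
        mean_series=values.mean(axis=0),
    )
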