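"""Mean/difference decomposition, rotated bases, and spectral statistics.

For a dyad with activity a1(t), a2(t), the mean component is
aM = (a1 + a2) / 2 and the difference component is aD = (a1 - a2) / 2
(halved so both components share the same scale). These are the eigenvector
coordinates of the symmetric coupling matrix used by the dynamical model, so
most statistics here come in mean/difference pairs: variance (magnitude) and
power spectral centroid (timescale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ActivityTimeSeries

__all__ = [
    "ComponentPair",
    "SpectralSummary",
    "decompose_pair",
    "reconstruct_pair",
    "rotation_matrix",
    "rotate_activity",
    "rotated_coupling",
    "interbrain_correlation",
    "correlation_from_components",
    "spectral_summary",
    "autocorrelation",
]


@dataclass
class ComponentPair:
    """Mean and difference component series of a dyadic recording."""

    times: np.ndarray
    mean: np.ndarray
    diff: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def variance_ratio(self) -> float:
        """Var(mean) / Var(difference), population normalization."""
        return float(np.var(self.mean) / np.var(self.diff))

    def centroid_ratio(self) -> float:
        """Centroid(mean) / centroid(difference), in Hz (ratio is unitless)."""
        cm = spectral_summary(self.mean, self.dt).centroid_hz
        cd = spectral_summary(self.diff, self.dt).centroid_hz
        return cm / cd


@dataclass(frozen=True)
class SpectralSummary:
    """Variance (squared activity units) and power spectral centroid (Hz)."""

    variance: float
    centroid_hz: float


def decompose_pair(activity: ActivityTimeSeries) -> ComponentPair:
    """Mean/difference change of basis for a two-subject recording."""
    if activity.n_subjects != 2:
        raise ValueError(
            f"decompose_pair requires exactly 2 subjects, got {activity.n_subjects}"
        )
    a1, a2 = activity.values
    return ComponentPair(
        times=activity.times.copy(), mean=(a1 + a2) / 2.0, diff=(a1 - a2) / 2.0
    )


def reconstruct_pair(
    pair: ComponentPair, subject_ids: tuple[str, str] = ("subject1", "subject2")
) -> ActivityTimeSeries:
    """Invert decompose_pair: a1 = aM + aD, a2 = aM - aD."""
    return ActivityTimeSeries(
        times=pair.times.copy(),
        values=np.vstack([pair.mean + pair.diff, pair.mean - pair.diff]),
        subject_ids=subject_ids,
    )


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """Counter-clockwise 2x2 rotation U; its columns are the new basis."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def rotate_activity(activity: ActivityTimeSeries, angle_deg: float) -> ActivityTimeSeries:
    """Express a dyadic recording in a basis rotated by ``angle_deg``.

    The new coordinates are a' = U^-1 a with U the rotation matrix; at 45
    degrees they are proportional (by sqrt(2)) to the mean and difference
    components.
    """
    if activity.n_subjects != 2:
        raise ValueError("rotate_activity requires exactly 2 subjects")
    u = rotation_matrix(angle_deg)
    rotated = u.T @ activity.values  # U orthogonal: U^-1 = U^T
    ids = tuple(f"{sid}_rot{angle_deg:g}" for sid in activity.subject_ids)
    return ActivityTimeSeries(times=activity.times.copy(), values=rotated, subject_ids=ids)


def rotated_coupling(cs: float, ci: float, angle_deg: float) -> float:
    """Across-variable coupling after rotating the activity basis.

    Returns the off-diagonal element of U^-1 C U for the dyadic coupling
    matrix C = [[-CS, CI], [CI, -CS]]. Equals CI*cos(2*theta), vanishing at
    45 degrees where the rotated variables are the mean and difference
    components.
    """
    if cs <= 0 or not 0 <= ci < cs:
        raise ValueError(
            f"stability constraint violated: 0 <= CI < CS required "
            f"(got CI={ci}, CS={cs})"
        )
    c = np.array([[-cs, ci], [ci, -cs]])
    u = rotation_matrix(angle_deg)
    return float((u.T @ c @ u)[0, 1])


def interbrain_correlation(a1: np.ndarray, a2: np.ndarray) -> float:
    """Pearson correlation between two activity series."""
    a1 = np.asarray(a1, float)
    a2 = np.asarray(a2, float)
    if a1.shape != a2.shape or a1.ndim != 1 or a1.size < 3:
        raise ValueError("series must be 1-D, equal length >= 3")
    x = a1 - a1.mean()
    y = a2 - a2.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(x @ y / (nx * ny))


def correlation_from_components(pair: ComponentPair) -> float:
    """Inter-brain correlation evaluated from the component inner products.

    correlation = (Mh.Mh - Dh.Dh) / sqrt((Mh.Mh + Dh.Dh)^2 - 4 (Mh.Dh)^2)
    where Mh, Dh are the time-mean-subtracted mean and difference components.
    Agrees with the direct Pearson correlation to round-off. The sign of the
    numerator shows that positive correlation is equivalent to the mean
    component having larger variance than the difference component.
    """
    mh = pair.mean - pair.mean.mean()
    dh = pair.diff - pair.diff.mean()
    mm = mh @ mh
    dd = dh @ dh
    md = mh @ dh
    denom_sq = (mm + dd) ** 2 - 4.0 * md**2
    if denom_sq <= 0:
        raise ValueError("correlation undefined: zero denominator")
    return float((mm - dd) / np.sqrt(denom_sq))


def _windowed_periodogram(series: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-subtracted, Hamming-windowed series.

    Frequencies on the grid k/(N*dt), k = 1..floor(N/2); the k = 0 bin is
    excluded (the series is mean-subtracted first, so it holds leakage only).
    """
    x = np.asarray(series, float)
    n = x.size
    x = (x - x.mean()) * np.hamming(n)
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, dt)
    return freqs[1:], power[1:]


def spectral_summary(series: np.ndarray, dt: float) -> SpectralSummary:
    """Variance and power spectral centroid of a single series.

    Variance is the plain (1/N) sample variance of the raw series. The
    centroid is the power-weighted average frequency of the mean-subtracted,
    Hamming-windowed periodogram over positive-frequency bins; it is
    invariant to offset and positive scaling of the series.
    """
    series = np.asarray(series, float)
    if series.ndim != 1 or series.size < 8:
        raise ValueError("series must be 1-D with length >= 8")
    variance = float(np.var(series))
    freqs, power = _windowed_periodogram(series, dt)
    total = power.sum()
    if total == 0:
        raise ValueError("centroid undefined: zero spectrum (constant series)")
    return SpectralSummary(variance=variance, centroid_hz=float((freqs * power).sum() / total))


def autocorrelation(series: np.ndarray, max_lag_s: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Peak-normalized autocorrelation after subtracting the time average.

    Biased (divide-by-N) estimator, normalized to 1 at lag zero. Returns
    (lags_s, values) for lags 0, dt, ..., max_lag_s.
    """
    x = np.asarray(series, float)
    max_lag = int(round(max_lag_s / dt))
    if x.ndim != 1 or x.size <= max_lag:
        raise ValueError("series must be longer than max_lag / dt")
    x = x - x.mean()
    denom = x @ x
    if denom == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    vals = np.array([x[: x.size - k] @ x[k:] for k in range(max_lag + 1)]) / denom
    lags = np.arange(max_lag + 1) * dt
    return lags, vals
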