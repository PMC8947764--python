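"""Closed-form analytics of the reduced (flat-spectrum-input) model.

In the eigenbasis the dyadic model decouples into two scalar equations,

    tau * daM/dt = -(CS - CI) aM + bM,   tau * daD/dt = -(CS + CI) aD + bD.

When bM and bD are noise with identical flat power spectra, the components
are Ornstein-Uhlenbeck processes and the variance ratio and power spectral
centroid ratio depend only on the coupling parameters:

    rVar  ~ (CS + CI) / (CS - CI),    rPSC ~ (CS - CI) / (CS + CI),

the second holding asymptotically in the frequency truncation (the centroid
sums diverge and their ratio approaches 1 only logarithmically; see
docs/methods.md). Inverting either form yields a coupling estimate from a
measured ratio. The module also implements the frequency-domain gradients
of rVar and rPSC with respect to the modulation power spectra, and the
covariance of their changes under random spherical perturbations, which
predicts the local linear trend relating the two ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .decomposition import ComponentPair

__all__ = [
    "ReducedSpec",
    "CouplingEstimate",
    "GradientAnalysis",
    "analytic_ratios",
    "recover_coupling",
    "decay_spectrum",
    "variance_closed_form",
    "simulate_reduced",
    "spectra_ratios",
    "ratio_gradients",
    "perturbation_trend",
]


@dataclass(frozen=True)
class ReducedSpec:
    """Parameters of the reduced model.

    ``p`` is the (flat) spectral density of the modulation noise driving
    each component; it cancels from every ratio. ``tau`` is absorbable into
    the couplings and defaults to 1 for pure analytics; simulations of the
    full parameter set pass the model's tau explicitly.
    """

    cs: float = 1.0
    ci: float = 0.4
    tau: float = 1.0
    duration_s: float = 6000.0
    p: float = 1.0
    dt: float = 2.5

    def __post_init__(self) -> None:
        if self.cs <= 0 or not 0 <= self.ci < self.cs:
            raise ValueError(
                f"stability constraint violated: 0 <= CI < CS required "
                f"(got CI={self.ci}, CS={self.cs})"
            )
        if self.duration_s <= 0 or self.p <= 0 or self.dt <= 0 or self.tau <= 0:
            raise ValueError("duration_s, p, dt, tau must be > 0")

    @property
    def lambda_mean(self) -> float:
        """Mean-component eigenvalue -(CS - CI) / tau, in 1/s."""
        return -(self.cs - self.ci) / self.tau

    @property
    def lambda_diff(self) -> float:
        """Difference-component eigenvalue -(CS + CI) / tau, in 1/s."""
        return -(self.cs + self.ci) / self.tau


@dataclass(frozen=True)
class CouplingEstimate:
    """A recovered CI with a validity flag (no silent clamping)."""

    value: float
    in_bounds: bool


@dataclass
class GradientAnalysis:
    """Perturbation analysis of (rVar, rPSC) around a working point."""

    covariance: np.ndarray  # 2x2
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    trend_slope: float  # d(rPSC)/d(rVar) along the leading eigenvector
    kt: int


def analytic_ratios(cs: float, ci: float) -> tuple[float, float]:
    """Large-T closed forms: rVar = (CS+CI)/(CS-CI), rPSC = (CS-CI)/(CS+CI)."""
    if cs <= 0 or not 0 <= ci < cs:
        raise ValueError(
            f"stability constraint violated: 0 <= CI < CS required "
            f"(got CI={ci}, CS={cs})"
        )
    rvar = (cs + ci) / (cs - ci)
    return rvar, 1.0 / rvar


def recover_coupling(ratio: float, cs: float, source: str = "variance") -> CouplingEstimate:
    """Invert an analytic ratio to an across-brain coupling estimate.

    source="variance": CI = CS*(r-1)/(r+1); source="centroid":
    CI = CS*(1-r)/(1+r). Estimates outside [0, CS) are returned flagged.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if source == "variance":
        ci = cs * (ratio - 1.0) / (ratio + 1.0)
    elif source == "centroid":
        ci = cs * (1.0 - ratio) / (1.0 + ratio)
    else:
        raise ValueError("source must be 'variance' or 'centroid'")
    return CouplingEstimate(value=float(ci), in_bounds=bool(0 <= ci < cs))


def decay_spectrum(lam: float, duration_s: float, kt: int) -> np.ndarray:
    """Power of the Fourier coefficients of the neural decay function.

    For f(t) = e^(lam*t) on [0, T], the coefficient at frequency k/T is
    f_k = (1/T) (e^(lam*T) - 1) / (lam - i*2*pi*k/T); returns |f_k|^2 for
    k = 1..kt. Positive and strictly decreasing in k.
    """
    if lam >= 0:
        raise ValueError("lam must be negative (stable decay)")
    if duration_s <= 0 or kt < 1:
        raise ValueError("duration_s > 0 and kt >= 1 required")
    k = np.arange(1, kt + 1)
    num = (np.expm1(lam * duration_s) / duration_s) ** 2
    return num / (lam**2 + (2.0 * np.pi * k / duration_s) ** 2)


def variance_closed_form(lam: float, duration_s: float, p: float, large_t: bool = False) -> float:
    """Component variance under flat-spectrum drive.

    The finite-T expression is
    p*(1/(2 lam) - 1/(T lam^2))*(e^(2 lam T) - 1) + 2 p e^(lam T)/(T lam^2);
    for large T it reduces to -p / (2 lam), the stationary
    Ornstein-Uhlenbeck variance.
    """
    if lam >= 0:
        raise ValueError("lam must be negative")
    if large_t:
        return -p / (2.0 * lam)
    t = duration_s
    return float(
        p * (1.0 / (2.0 * lam) - 1.0 / (t * lam**2)) * np.expm1(2.0 * lam * t)
        + 2.0 * p * np.exp(lam * t) / (t * lam**2)
    )


def _simulate_ou(lam: float, n_bins: int, dt: float, p: float, rng: np.random.Generator) -> np.ndarray:
    """Exact discretization of da/dt = lam*a + xi, xi white with density p.

    The per-step innovation is i.i.d. Gaussian with variance
    p*(e^(2 lam dt) - 1)/(2 lam), which makes the sampled process the exact
    stationary-law recursion a_{k+1} = e^(lam dt) a_k + eta_k from a(0) = 0.
    """
    e = np.exp(lam * dt)
    sd = np.sqrt(p * np.expm1(2.0 * lam * dt) / (2.0 * lam))
    eta = rng.normal(0.0, sd, n_bins)
    return lfilter([1.0], [1.0, -e], eta)


def simulate_reduced(spec: ReducedSpec, seed: int | np.random.Generator) -> ComponentPair:
    """Simulate the two decoupled component equations under flat-spectrum drive.

    Each component is advanced with the exact Ornstein-Uhlenbeck update at
    the grid step, driven by independent white noise of equal spectral
    density p, starting from 0. Returns the sampled mean and difference
    component series.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = int(round(spec.duration_s / spec.dt))
    # forcing b/tau has spectral density p/tau^2
    density = spec.p / spec.tau**2
    mean = _simulate_ou(spec.lambda_mean, n_bins, spec.dt, density, rng)
    diff = _simulate_ou(spec.lambda_diff, n_bins, spec.dt, density, rng)
    return ComponentPair(times=np.arange(n_bins) * spec.dt, mean=mean, diff=diff)


def spectra_ratios(
    b_mean: np.ndarray, b_diff: np.ndarray, f_mean: np.ndarray, f_diff: np.ndarray
) -> tuple[float, float]:
    """(rVar, rPSC) from modulation power spectra B and decay spectra F.

    rVar = sum(BM*FM) / sum(BD*FD);
    rPSC = [sum(k BM FM)/sum(BM FM)] / [sum(k BD FD)/sum(BD FD)]
    with k the frequency index 1..kt.
    """
    k = np.arange(1, b_mean.size + 1)
    sm = b_mean @ f_mean
    sd = b_diff @ f_diff
    rvar = sm / sd
    rpsc = ((k * b_mean) @ f_mean / sm) / ((k * b_diff) @ f_diff / sd)
    return float(rvar), float(rpsc)


def ratio_gradients(
    b_mean: np.ndarray, b_diff: np.ndarray, f_mean: np.ndarray, f_diff: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of rVar and rPSC w.r.t. the concatenated spectra (BM, BD).

    Implements the four partial-derivative families:
      d rVar / d BM_k =  FM_k / sum(BD FD)
      d rVar / d BD_k = -sum(BM FM) / sum(BD FD)^2 * FD_k
      d rPSC / d BM_k =  [sum(BD FD) / (sum(BM FM) sum(q BD FD))] * FM_k
                         * (k - sum(p BM FM)/sum(BM FM))
      d rPSC / d BD_k =  [sum(p BM FM) / (sum(BM FM) sum(l BD FD))] * FD_k
                         * (1 - k sum(BD FD)/sum(q BD FD))
    """
    for arr in (b_mean, b_diff, f_mean, f_diff):
        if np.any(np.asarray(arr) <= 0):
            raise ValueError("spectra must be strictly positive")
    if not b_mean.size == b_diff.size == f_mean.size == f_diff.size:
        raise ValueError("all spectra must share the truncation length kt")
    k = np.arange(1, b_mean.size + 1)
    sm = b_mean @ f_mean
    sd = b_diff @ f_diff
    skm = (k * b_mean) @ f_mean
    skd = (k * b_diff) @ f_diff
    grad_rvar = np.concatenate([f_mean / sd, -(sm / sd**2) * f_diff])
    gm = (sd / (sm * skd)) * f_mean * (k - skm / sm)
    gd = (skm / (sm * skd)) * f_diff * (1.0 - k * sd / skd)
    grad_rpsc = np.concatenate([gm, gd])
    return grad_rvar, grad_rpsc


def perturbation_trend(
    grad_rvar: np.ndarray, grad_rpsc: np.ndarray, delta_norm: float, kt: int
) -> GradientAnalysis:
    """Covariance of (d rVar, d rPSC) under uniform spherical perturbations.

    For dB uniform on the radius-``delta_norm`` sphere in 2*kt dimensions,
    the covariance of (dB.grad_rVar, dB.grad_rPSC) is
    ||dB||^2 / (2 kt) times the gradient Gram matrix. The leading
    eigenvector gives the direction of the local linear trend; trend_slope
    is its rPSC/rVar component ratio.
    """
    if grad_rvar.size != 2 * kt or grad_rpsc.size != 2 * kt:
        raise ValueError("gradients must have length 2*kt")
    if np.all(grad_rvar == 0) and np.all(grad_rpsc == 0):
        raise ValueError("zero gradients: perturbation covariance undefined")
    gram = np.array(
        [
            [grad_rvar @ grad_rvar, grad_rvar @ grad_rpsc],
            [grad_rvar @ grad_rpsc, grad_rpsc @ grad_rpsc],
        ]
    )
    cov = (delta_norm**2 / (2.0 * kt)) * gram
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lead = evecs[:, 0]
    slope = float(lead[1] / lead[0]) if lead[0] != 0 else float("inf")
    return GradientAnalysis(
        covariance=cov, eigenvalues=evals, eigenvectors=evecs,
        trend_slope=slope, kt=kt,
    )
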