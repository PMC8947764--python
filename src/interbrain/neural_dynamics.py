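"""The coupled linear model of inter-brain neural dynamics.

Activity of n subjects evolves as

    tau * da/dt = C a(t) + b(t)

where C has -CS (functional self-coupling) on the diagonal and CI
(functional across-brain coupling) off it, and b(t) is behavioral
modulation: a per-behavior level plus a constant offset, with i.i.d.
Gaussian noise per subject per bin, linearly interpolated between 2.5-s
grid points. C is symmetric: the all-ones direction (mean component) is an
eigenvector with eigenvalue (n-1)*CI - CS, and every direction orthogonal
to it (the difference subspace) has eigenvalue -CI - CS. Stability requires
0 <= (n-1)*CI < CS.

Because the system is linear and b(t) is piecewise linear, each grid step
has an exact closed-form update (exponential-integrator coefficients in the
eigenbasis, evaluated as a linear recurrence); this is the default
integrator. An adaptive Runge-Kutta route is kept for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import lfilter, lfiltic

from .behavior_model import MarkovChainModel, simulate_behavior
from .core_io import (
    DEFAULT_MODULATION_LEVELS,
    ActivityTimeSeries,
    BehaviorSequence,
    RunConfig,
    stage_rng,
)

__all__ = [
    "CouplingSpec",
    "ModulationMap",
    "ModulationSeries",
    "Session",
    "build_coupling_matrix",
    "modulation_from_behavior",
    "fixed_point",
    "simulate_dynamics",
    "simulate_session",
    "generate_group_modulation",
    "simulate_group_session",
    "moving_average",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Functional coupling parameters of the n-subject model."""

    cs: float = 1.0
    ci: float = 0.4
    tau: float = 15.0
    n: int = 2

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.cs <= 0 or not 0 <= (self.n - 1) * self.ci < self.cs:
            raise ValueError(
                "stability constraint violated: 0 <= (n-1)*CI < CS required "
                f"(got CS={self.cs}, CI={self.ci}, n={self.n})"
            )


@dataclass(frozen=True)
class ModulationMap:
    """Per-behavior modulation levels, offset, and noise scale."""

    levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODULATION_LEVELS)
    )
    bconstant: float = -0.08
    sigma_n: float = 0.15

    @classmethod
    def from_config(cls, config: RunConfig) -> "ModulationMap":
        return cls(
            levels=dict(config.modulation),
            bconstant=config.bconstant,
            sigma_n=config.sigma_n,
        )


@dataclass
class ModulationSeries:
    """Behavioral modulation b = bd + bn on the simulation grid.

    ``bd`` is the deterministic part (behavior level + bconstant per subject
    per bin) and ``bn`` the Gaussian modulation noise; between grid points
    the model evaluates b(t) by linear interpolation.
    """

    times: np.ndarray
    bd: np.ndarray  # (n_subjects, n_bins)
    bn: np.ndarray  # (n_subjects, n_bins)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.bd = np.atleast_2d(np.asarray(self.bd, float))
        self.bn = np.atleast_2d(np.asarray(self.bn, float))
        if self.bd.shape != self.bn.shape or self.bd.shape[1] != self.times.size:
            raise ValueError("bd and bn must share shape (n_subjects, n_bins)")

    @property
    def b(self) -> np.ndarray:
        return self.bd + self.bn

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_subjects(self) -> int:
        return self.bd.shape[0]


@dataclass
class Session:
    """A complete simulated session: behavior, modulation, activity."""

    behavior: BehaviorSequence | None
    modulation: ModulationSeries
    activity: ActivityTimeSeries
    spec: CouplingSpec
    seed: int | None = None


def build_coupling_matrix(spec: CouplingSpec) -> np.ndarray:
    """The n x n functional coupling matrix: -CS diagonal, CI off-diagonal."""
    c = np.full((spec.n, spec.n), spec.ci)
    np.fill_diagonal(c, -spec.cs)
    return c


def modulation_from_behavior(
    behavior: BehaviorSequence,
    modmap: ModulationMap,
    rng: int | np.random.Generator,
) -> ModulationSeries:
    """Build b(t) from a behavior sequence.

    bd per bin is the behavior's modulation level plus bconstant; bn is
    i.i.d. Gaussian(0, sigma_n^2) per subject per bin.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    missing = {
        lab for row in behavior.labels for lab in row if lab not in modmap.levels
    }
    if missing:
        raise ValueError(f"behaviors without a modulation level: {sorted(missing)}")
    lookup = {k: v + modmap.bconstant for k, v in modmap.levels.items()}
    bd = np.vectorize(lookup.__getitem__, otypes=[float])(behavior.labels)
    bn = rng.normal(0.0, modmap.sigma_n, size=bd.shape)
    return ModulationSeries(times=behavior.times.copy(), bd=bd, bn=bn)


def fixed_point(c: np.ndarray, bd0: np.ndarray) -> np.ndarray:
    """The equilibrium a with C a + bd0 = 0 (C invertible under stability)."""
    return np.linalg.solve(c, -np.asarray(bd0, float))


def _phi12(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-integrator coefficients phi1 = (e^z-1)/z, phi2 = (e^z-1-z)/z^2."""
    z = np.asarray(z, float)
    e = np.exp(z)
    return (e - 1.0) / z, (e - 1.0 - z) / z**2


def simulate_dynamics(
    spec: CouplingSpec,
    modulation: ModulationSeries,
    method: str = "exact",
    subject_ids: tuple[str, ...] | None = None,
) -> ActivityTimeSeries:
    """Integrate tau * da/dt = C a + b(t) from the noiseless fixed point.

    b(t) is the piecewise-linear interpolant of ``modulation.b``; the
    initial condition is the fixed point of the *noiseless* modulation at
    the first bin, a(0) = -C^-1 bd(0). Output is sampled exactly on the
    modulation grid.

    method="exact" uses the closed-form per-step update in the eigenbasis of
    C (the system is linear, so this is exact to round-off); method="rk45"
    integrates with an adaptive Runge-Kutta scheme (rtol 1e-8, atol 1e-10)
    for cross-validation.
    """
    if modulation.n_subjects != spec.n:
        raise ValueError(
            f"modulation has {modulation.n_subjects} subjects, spec.n={spec.n}"
        )
    c = build_coupling_matrix(spec)
    b = modulation.b
    a0 = fixed_point(c, modulation.bd[:, 0])
    h = modulation.dt
    times = modulation.times

    if method == "exact":
        lam, q = np.linalg.eigh(c)  # C symmetric
        mu = lam / spec.tau
        g = (q.T @ b) / spec.tau  # forcing in the eigenbasis
        z = mu * h
        e = np.exp(z)
        phi1, phi2 = _phi12(z)
        # per-channel update: y_{k+1} = e*y_k + h*(phi1*g_k + phi2*(g_{k+1}-g_k))
        drive = h * (phi1[:, None] * g[:, :-1] + phi2[:, None] * np.diff(g, axis=1))
        y0 = q.T @ a0
        y = np.empty_like(g)
        y[:, 0] = y0
        for i in range(spec.n):
            zi = lfiltic([1.0], [1.0, -e[i]], [y0[i]])
            y[i, 1:], _ = lfilter([1.0], [1.0, -e[i]], drive[i], zi=zi)
        values = q @ y
    elif method == "rk45":
        # b(t) has derivative kinks at every grid knot, so integrate
        # knot-to-knot (b is linear within each segment)
        slopes = np.diff(b, axis=1) / h
        values = np.empty_like(b)
        values[:, 0] = a0
        state = a0
        for k in range(b.shape[1] - 1):
            bk = b[:, k]
            sk = slopes[:, k]
            tk = times[k]
            sol = solve_ivp(
                lambda t, a: (c @ a + bk + sk * (t - tk)) / spec.tau,
                (tk, times[k + 1]),
                state,
                method="RK45",
                rtol=1e-8,
                atol=1e-10,
            )
            if not sol.success:
                raise RuntimeError(f"integration failed: {sol.message}")
            state = sol.y[:, -1]
            values[:, k + 1] = state
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(values)):
        raise AssertionError("non-finite activity from a stable linear system")
    ids = subject_ids or tuple(f"bat{i + 1}" for i in range(spec.n))
    return ActivityTimeSeries(times=times.copy(), values=values, subject_ids=ids)


def simulate_session(
    config: RunConfig,
    behavior_model: MarkovChainModel,
    seed: int | None = None,
) -> Session:
    """End-to-end two-subject session: behavior -> b(t) -> a(t).

    Per-stage generators are derived deterministically from the seed, so
    runs with equal (config, seed) are bit-identical.
    """
    seed = config.seed if seed is None else seed
    spec = CouplingSpec(cs=config.cs, ci=config.ci, tau=config.tau, n=2)
    behavior = simulate_behavior(
        behavior_model, config.n_bins, stage_rng(seed, "behavior"), dt=config.dt
    )
    modmap = ModulationMap.from_config(config)
    modulation = modulation_from_behavior(
        behavior, modmap, stage_rng(seed, "modulation")
    )
    activity = simulate_dynamics(spec, modulation, subject_ids=behavior.subject_ids)
    return Session(
        behavior=behavior, modulation=modulation, activity=activity,
        spec=spec, seed=seed,
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window truncated at the edges."""
    if window <= 0:
        raise ValueError("window must be positive")
    x = np.asarray(x, float)
    kernel = np.ones(window)
    # centered slice of the full convolution so a window wider than the
    # series still averages over the available points
    num = np.convolve(x, kernel, mode="full")
    den = np.convolve(np.ones_like(x), kernel, mode="full")
    start = (window - 1) // 2
    sl = slice(start, start + x.size)
    return num[sl] / den[sl]


def generate_group_modulation(
    n: int,
    duration_s: float,
    bmean: float = 0.2,
    bstd: float = 3.5,
    smoothing_window: int = 1200,
    sigma_n: float = 0.15,
    dt: float = 2.5,
    rng: int | np.random.Generator = 0,
) -> ModulationSeries:
    """Smoothed-noise modulation for the n-subject (group) model.

    Per subject, independently: i.i.d. Gaussian(bmean, bstd^2) values at the
    grid, smoothed with a ``smoothing_window``-point moving average (edges
    truncated), then independent Gaussian(0, sigma_n^2) noise added.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_bins = int(round(duration_s / dt))
    if n_bins < 2:
        raise ValueError("duration too short for the grid")
    bd = np.stack(
        [
            moving_average(rng.normal(bmean, bstd, n_bins), smoothing_window)
            for _ in range(n)
        ]
    )
    bn = rng.normal(0.0, sigma_n, size=bd.shape)
    return ModulationSeries(times=np.arange(n_bins) * dt, bd=bd, bn=bn)


def simulate_group_session(
    spec: CouplingSpec,
    duration_s: float = 6000.0,
    seed: int = 0,
    bmean: float = 0.2,
    bstd: float = 3.5,
    smoothing_window: int = 1200,
    sigma_n: float = 0.15,
    dt: float = 2.5,
) -> Session:
    """Full n-subject group session with smoothed-noise modulation."""
    modulation = generate_group_modulation(
        spec.n, duration_s, bmean=bmean, bstd=bstd,
        smoothing_window=smoothing_window, sigma_n=sigma_n, dt=dt,
        rng=stage_rng(seed, "group-modulation"),
    )
    activity = simulate_dynamics(spec, modulation)
    return Session(
        behavior=None, modulation=modulation, activity=activity,
        spec=spec, seed=seed,
    )
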