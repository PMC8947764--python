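"""Synthetic behavior chains and session ensembles.

Stand-in for recorded dyadic sessions: joint behavior chains over the
11-behavior vocabulary with a controllable tendency toward coordinated
(same-behavior) states, calibratable to a target stationary same-behavior
probability (0.58 for one-chamber-like chains); full pseudo-sessions built
through the dynamical model; and paired coupled/uncoupled controls sharing
the identical behavioral modulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace
from typing import Mapping

import numpy as np

from .behavior_model import (
    JointState,
    MarkovChainModel,
    same_behavior_probability,
    stationary_distribution,
)
from .core_io import BehaviorVocabulary, RunConfig, stage_rng
from .neural_dynamics import Session, simulate_dynamics, simulate_session

__all__ = [
    "SynthChainSpec",
    "bat_like_weights",
    "synth_transition_matrix",
    "synth_session_ensemble",
    "synth_uncoupled_control",
]

_MAX_TILT = 10.0


@dataclass(frozen=True)
class SynthChainSpec:
    """Specification of a synthetic joint behavior chain.

    ``persistence`` is the per-step probability a subject repeats its
    behavior; the default 0.97 gives behavioral bouts of ~80 s (mean dwell
    2.5 s / (1 - persistence)), a typical ethogram bout scale, and keeps
    coordinated and non-coordinated epochs long relative to the model's
    10-25 s neural time constants (behavior switching bin-to-bin is not a
    feature of annotated sessions; see docs/methods.md for the calibration).
    ``coordination`` is an exponential tilt toward same-behavior joint
    states (0 = independent subjects); ``target_same_prob``, when given,
    calibrates the tilt by bisection to the requested stationary
    same-behavior probability. ``marginal_weights`` optionally biases which
    behavior a subject switches to (default uniform).
    """

    vocabulary: BehaviorVocabulary = BehaviorVocabulary()
    persistence: float = 0.97
    coordination: float = 0.0
    target_same_prob: float | None = None
    marginal_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError(
                "persistence must be in [0, 1); persistence = 1 gives a "
                "reducible (frozen) chain"
            )
        if self.target_same_prob is not None and not 0 < self.target_same_prob < 1:
            raise ValueError("target_same_prob must be in (0, 1)")


def bat_like_weights(vocabulary: BehaviorVocabulary | None = None) -> dict[str, float]:
    """Marginal switch-target weights loosely echoing captive-bat ethograms.

    Resting, active non-social, and self-grooming dominate; social behaviors
    are rarer. Qualitative only — no fidelity to any recorded session is
    claimed.
    """
    vocab = vocabulary or BehaviorVocabulary()
    heavy = {"resting": 6.0, "active non-social": 3.0, "self-grooming": 2.0}
    return {name: heavy.get(name, 1.0) for name in vocab.names}


def _marginal_matrix(spec: SynthChainSpec) -> np.ndarray:
    names = spec.vocabulary.names
    k = len(names)
    w = np.array(
        [
            (spec.marginal_weights or {}).get(name, 1.0)
            for name in names
        ],
        float,
    )
    if np.any(w <= 0):
        raise ValueError("marginal weights must be positive")
    p = np.zeros((k, k))
    for i in range(k):
        off = w.copy()
        off[i] = 0.0
        off = off / off.sum() * (1.0 - spec.persistence)
        p[i] = off
        p[i, i] = spec.persistence
    return p


def _joint_chain(spec: SynthChainSpec, tilt: float) -> tuple[list[JointState], np.ndarray]:
    names = spec.vocabulary.names
    pm = _marginal_matrix(spec)
    states = list(itertools.product(names, names))
    k = len(names)
    # product chain, rows tilted toward same-behavior target states
    prod = np.kron(pm, pm)
    same = np.array([1.0 if s[0] == s[1] else 0.0 for s in states])
    trans = prod * np.exp(tilt * same)[None, :]
    trans = trans / trans.sum(axis=1, keepdims=True)
    return states, trans


def _stationary_same_prob(spec: SynthChainSpec, tilt: float) -> float:
    states, trans = _joint_chain(spec, tilt)
    model = MarkovChainModel(
        order=1, states=states, vocabulary=spec.vocabulary,
        transition=trans, initial=np.full(len(states), 1.0 / len(states)),
    )
    return same_behavior_probability(stationary_distribution(model), states)


def synth_transition_matrix(spec: SynthChainSpec) -> MarkovChainModel:
    """Build (and optionally calibrate) an order-1 joint behavior chain.

    The chain is the product of two independent per-subject chains, with
    each row exponentially tilted toward same-behavior joint states by the
    coordination parameter and renormalized. With ``target_same_prob`` set,
    the tilt is found by bisection so the stationary same-behavior
    probability lands within 0.01 of the target. The initial distribution
    is uniform over the joint state space.
    """
    tilt = spec.coordination
    if spec.target_same_prob is not None:
        lo, hi = -_MAX_TILT, _MAX_TILT
        p_lo = _stationary_same_prob(spec, lo)
        p_hi = _stationary_same_prob(spec, hi)
        if not p_lo <= spec.target_same_prob <= p_hi:
            raise ValueError(
                f"target_same_prob={spec.target_same_prob} unattainable; "
                f"achievable range at this persistence is "
                f"[{p_lo:.4f}, {p_hi:.4f}]"
            )
        for _ in range(60):
            tilt = (lo + hi) / 2.0
            if _stationary_same_prob(spec, tilt) < spec.target_same_prob:
                lo = tilt
            else:
                hi = tilt
            if hi - lo < 1e-10:
                break
        tilt = (lo + hi) / 2.0
    states, trans = _joint_chain(spec, tilt)
    return MarkovChainModel(
        order=1, states=states, vocabulary=spec.vocabulary,
        transition=trans,
        initial=np.full(len(states), 1.0 / len(states)),
    )


def synth_session_ensemble(
    config: RunConfig,
    chain: MarkovChainModel,
    n_sessions: int,
    seed: int = 0,
) -> list[Session]:
    """Independent full sessions (behavior + modulation + activity).

    Session seeds are derived deterministically from the master seed, so the
    ensemble is fully reproducible from (config, chain, seed).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    child_seeds = stage_rng(seed, "ensemble").integers(0, 2**31 - 1, size=n_sessions)
    return [
        simulate_session(config, chain, seed=int(s)) for s in child_seeds
    ]


def synth_uncoupled_control(session: Session) -> Session:
    """Re-integrate a session with CI = 0 under the identical b(t).

    The control shares the coupled session's behavior and the bit-identical
    modulation realization (deterministic part and noise); only the
    across-brain coupling is removed, enabling paired contrasts.
    """
    if session.modulation is None:
        raise ValueError("session has no stored modulation series")
    spec0 = dc_replace(session.spec, ci=0.0)
    activity = simulate_dynamics(
        spec0, session.modulation, subject_ids=session.activity.subject_ids
    )
    return Session(
        behavior=session.behavior, modulation=session.modulation,
        activity=activity, spec=spec0, seed=session.seed,
    )
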