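"""Markov-chain models of joint two-subject behavior.

Each chain state is the pair of behavior labels of the two subjects at one
2.5-s bin. Fitting pools transition counts across sessions, optionally with
symmetry pooling (the count for AB -> CD and the count for BA -> DC are each
taken to be their sum, so the two subjects are statistically exchangeable),
and excludes rarely-visited states. Order-0 (independent), order-1 (Markov)
and order-2 models are supported for held-out likelihood comparison with
Laplace smoothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_io import BehaviorSequence, BehaviorVocabulary

__all__ = [
    "JointState",
    "MarkovChainModel",
    "fit_markov",
    "stationary_distribution",
    "same_behavior_probability",
    "simulate_behavior",
    "loglikelihood",
    "compare_orders",
]

JointState = tuple[str, str]

_ROW_TOL = 1e-12


@dataclass
class MarkovChainModel:
    """Joint-behavior chain of order 0, 1, or 2.

    ``states`` is the joint state space. For order 0, ``state_probs`` holds
    the marginal state probabilities. For order 1, ``transition`` is the
    row-stochastic matrix over ``states`` and ``initial`` the start
    distribution. For order 2, ``histories`` lists the observed
    (previous state, current state) pairs and ``transition2`` their rows
    over ``states``; unobserved histories fall back to the uniform row
    implied by Laplace smoothing of zero counts.
    """

    order: int
    states: list[JointState]
    vocabulary: BehaviorVocabulary
    smoothing_alpha: float = 0.0
    state_probs: np.ndarray | None = None
    transition: np.ndarray | None = None
    initial: np.ndarray | None = None
    histories: list[tuple[JointState, JointState]] = field(default_factory=list)
    transition2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1, or 2")
        for name, arr in (
            ("state_probs", self.state_probs),
            ("initial", self.initial),
        ):
            if arr is not None:
                if np.any(arr < 0) or abs(arr.sum() - 1.0) > _ROW_TOL * arr.size:
                    raise ValueError(f"{name} must be a probability vector")
        for name, mat in (("transition", self.transition), ("transition2", self.transition2)):
            if mat is not None:
                if np.any(mat < 0):
                    raise ValueError(f"{name} has negative entries")
                rows = mat.sum(axis=1)
                if np.any(np.abs(rows - 1.0) > 1e-10):
                    raise ValueError(f"{name} rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self) -> dict[JointState, int]:
        return {s: i for i, s in enumerate(self.states)}


def _joint_sequences(sessions: list[BehaviorSequence]) -> list[list[JointState]]:
    out = []
    for sess in sessions:
        if sess.n_subjects != 2:
            raise ValueError("behavior sessions must have exactly 2 subjects")
        out.append([(sess.labels[0, j], sess.labels[1, j]) for j in range(sess.n_bins)])
    return out


def _swap(s: JointState) -> JointState:
    return (s[1], s[0])


def fit_markov(
    sessions: list[BehaviorSequence],
    order: int = 1,
    symmetric: bool = False,
    min_transitions: int = 100,
    smoothing_alpha: float = 0.0,
    vocabulary: BehaviorVocabulary | None = None,
) -> MarkovChainModel:
    """Fit a joint-behavior chain from sessions pooled at the 2.5-s grid.

    With ``symmetric``, the count for AB -> CD and the count for BA -> DC are
    each replaced by their sum (self-symmetric transitions double). States
    with fewer than ``min_transitions`` outgoing transitions are excluded
    and the remaining rows renormalized (transitions into excluded states
    are dropped). ``smoothing_alpha`` pseudo-counts are added to every
    allowed cell before normalizing; with smoothing the state space is the
    full vocabulary product, so every symbol has support.
    """
    if not sessions:
        raise ValueError("sessions must be non-empty")
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1, or 2")
    vocab = vocabulary or sessions[0].vocabulary
    seqs = _joint_sequences(sessions)
    if order == 2 and min(len(s) for s in seqs) < 3:
        raise ValueError("order-2 fit requires sessions of length >= 3")

    if smoothing_alpha > 0:
        states = list(itertools.product(vocab.names, vocab.names))
    else:
        observed: set[JointState] = set()
        for seq in seqs:
            observed.update(seq)
            if symmetric:
                observed.update(_swap(s) for s in seq)
        states = sorted(observed)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)

    if order == 0:
        counts = np.zeros(n)
        for seq in seqs:
            for s in seq:
                counts[idx[s]] += 1
                if symmetric:
                    counts[idx[_swap(s)]] += 1
        counts += smoothing_alpha
        if counts.sum() == 0:
            raise ValueError("no observations")
        probs = counts / counts.sum()
        return MarkovChainModel(
            order=0, states=states, vocabulary=vocab,
            smoothing_alpha=smoothing_alpha, state_probs=probs,
        )

    if order == 1:
        counts = np.zeros((n, n))
        init = np.zeros(n)
        for seq in seqs:
            init[idx[seq[0]]] += 1
            if symmetric:
                init[idx[_swap(seq[0])]] += 1
            for a, b in zip(seq[:-1], seq[1:]):
                counts[idx[a], idx[b]] += 1
                if symmetric:
                    counts[idx[_swap(a)], idx[_swap(b)]] += 1
        if counts.sum() == 0:
            raise ValueError("no transitions observed")
        # State exclusion on pooled outgoing counts; dropping a state removes
        # transitions into it, which can cascade, so iterate to a fixed point.
        threshold = max(min_transitions, 1) if smoothing_alpha == 0 else min_transitions
        keep = np.ones(n, bool)
        while True:
            out_counts = counts[:, keep].sum(axis=1)
            new_keep = keep & (out_counts >= threshold)
            if new_keep.sum() == 0:
                raise ValueError(
                    "state exclusion removed every state; lower min_transitions"
                )
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
        kept = np.flatnonzero(keep)
        sub = counts[np.ix_(kept, kept)] + smoothing_alpha
        rows = sub.sum(axis=1)
        if np.any(rows == 0):
            raise ValueError("zero outgoing probability row after exclusion")
        trans = sub / rows[:, None]
        init_sub = init[kept] + smoothing_alpha
        if init_sub.sum() == 0:
            init_sub = np.ones(kept.size)
        init_sub = init_sub / init_sub.sum()
        return MarkovChainModel(
            order=1, states=[states[i] for i in kept], vocabulary=vocab,
            smoothing_alpha=smoothing_alpha, transition=trans, initial=init_sub,
        )

    # order == 2: histories restricted to observed (or swap-observed) pairs;
    # targets over the full state space when smoothing.
    hist_counts: dict[tuple[JointState, JointState], np.ndarray] = {}
    for seq in seqs:
        for a, b, c in zip(seq[:-2], seq[1:-1], seq[2:]):
            for h, t in (((a, b), c), ((_swap(a), _swap(b)), _swap(c))) if symmetric else (((a, b), c),):
                if h not in hist_counts:
                    hist_counts[h] = np.zeros(n)
                hist_counts[h][idx[t]] += 1
    if not hist_counts:
        raise ValueError("no order-2 transitions observed")
    histories = sorted(hist_counts)
    mat = np.stack([hist_counts[h] for h in histories]) + smoothing_alpha
    row_ok = mat.sum(axis=1) > 0
    histories = [h for h, ok in zip(histories, row_ok) if ok]
    mat = mat[row_ok]
    mat = mat / mat.sum(axis=1, keepdims=True)
    return MarkovChainModel(
        order=2, states=states, vocabulary=vocab,
        smoothing_alpha=smoothing_alpha, histories=histories, transition2=mat,
    )


def stationary_distribution(model: MarkovChainModel, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution pi with pi^T = pi^T P of an order-1 chain.

    Uniqueness requires the positive-probability graph to be strongly
    connected; reducible chains raise with the disconnected components
    named. Computed by eigen-decomposition with a power-iteration fallback.
    """
    if model.order != 1 or model.transition is None:
        raise ValueError("stationary_distribution requires an order-1 model")
    p = model.transition
    n_comp, labels = connected_components(csr_matrix(p > 0), connection="strong")
    if n_comp > 1:
        comps = [
            [model.states[i] for i in np.flatnonzero(labels == c)]
            for c in range(n_comp)
        ]
        raise ValueError(
            f"no unique stationary distribution: chain splits into "
            f"{n_comp} strongly connected components: {comps}"
        )
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    if np.any(pi < -1e-9) or np.linalg.norm(pi @ p - pi, np.inf) > tol:
        # eigen solve can struggle near degeneracy; refine by power iteration
        pi = np.full(p.shape[0], 1.0 / p.shape[0])
        for _ in range(100_000):
            nxt = pi @ p
            if np.linalg.norm(nxt - pi, np.inf) < tol / 10:
                pi = nxt
                break
            pi = nxt
        if np.linalg.norm(pi @ p - pi, np.inf) > tol:
            raise ValueError("stationary distribution did not converge")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def same_behavior_probability(
    distribution: np.ndarray, states: list[JointState]
) -> float:
    """Total probability of states where both subjects share one behavior."""
    distribution = np.asarray(distribution, float)
    if distribution.size != len(states):
        raise ValueError("distribution length must match the state list")
    return float(sum(p for p, s in zip(distribution, states) if s[0] == s[1]))


def simulate_behavior(
    model: MarkovChainModel,
    n_steps: int,
    seed: int | np.random.Generator,
    dt: float = 2.5,
    subject_ids: tuple[str, str] = ("bat1", "bat2"),
) -> BehaviorSequence:
    """Simulate a joint behavior sequence from an order-1 chain."""
    if model.order != 1 or model.transition is None or model.initial is None:
        raise ValueError("simulate_behavior requires a fitted order-1 model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum_init = np.cumsum(model.initial)
    cum_rows = np.cumsum(model.transition, axis=1)
    draws = rng.random(n_steps)
    path = np.empty(n_steps, dtype=int)
    path[0] = np.searchsorted(cum_init, draws[0], side="right")
    for t in range(1, n_steps):
        path[t] = np.searchsorted(cum_rows[path[t - 1]], draws[t], side="right")
    labels = np.empty((2, n_steps), dtype=object)
    for t, s in enumerate(path):
        labels[0, t], labels[1, t] = model.states[s]
    return BehaviorSequence(
        times=np.arange(n_steps) * dt,
        labels=labels,
        subject_ids=subject_ids,
        vocabulary=model.vocabulary,
    )


def loglikelihood(
    model: MarkovChainModel, sessions: list[BehaviorSequence], start: int = 2
) -> float:
    """Summed log-likelihood of sessions, scored from bin ``start`` onward.

    Scoring from a common start bin lets models of different order be
    compared on the same number of terms. Requires full support over the
    scored symbols (guaranteed when the model was fit with smoothing over
    the vocabulary product space).
    """
    idx = model.state_index()
    total = 0.0
    if model.order == 2:
        hist_idx = {h: i for i, h in enumerate(model.histories)}
        uniform = -np.log(model.n_states)
    for seq in _joint_sequences(sessions):
        for t in range(start, len(seq)):
            j = idx.get(seq[t])
            if j is None:
                raise ValueError(f"state {seq[t]!r} outside the model's support")
            if model.order == 0:
                p = model.state_probs[j]
            elif model.order == 1:
                p = model.transition[idx[seq[t - 1]], j]
            else:
                h = hist_idx.get((seq[t - 2], seq[t - 1]))
                if h is None:
                    total += uniform
                    continue
                p = model.transition2[h, j]
            if p <= 0:
                raise ValueError("zero-probability symbol; fit with smoothing")
            total += np.log(p)
    return float(total)


def compare_orders(
    sessions: list[BehaviorSequence],
    n_splits: int = 100,
    train_fraction: float = 0.8,
    smoothing_alpha: float = 1.0,
    seed: int = 0,
    orders: tuple[int, ...] = (0, 1, 2),
) -> pd.DataFrame:
    """Held-out likelihood comparison of behavior-model orders.

    For each random split, each order is fit on the training sessions with
    Laplace smoothing (no state exclusion) and scored by the summed
    log-likelihood of the held-out sessions. Returns a tidy frame with
    columns (split, order, loglik).
    """
    if len(sessions) < 5:
        raise ValueError("compare_orders requires at least 5 sessions")
    if smoothing_alpha <= 0:
        raise ValueError("compare_orders requires smoothing_alpha > 0")
    rng = np.random.default_rng(seed)
    n = len(sessions)
    n_train = max(1, min(n - 1, int(round(train_fraction * n))))
    rows = []
    for split in range(n_splits):
        perm = rng.permutation(n)
        train = [sessions[i] for i in perm[:n_train]]
        test = [sessions[i] for i in perm[n_train:]]
        for order in orders:
            model = fit_markov(
                train, order=order, symmetric=False, min_transitions=0,
                smoothing_alpha=smoothing_alpha,
            )
            rows.append(
                {"split": split, "order": order, "loglik": loglikelihood(model, test)}
            )
    return pd.DataFrame(rows)
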