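"""Binary-trait Markov machinery: equal-rates Mk fitting, stochastic character
mapping, and deterministic clade paintings for a-priori regime hypotheses.

The model is the symmetric two-state continuous-time Markov chain with a
single rate q (equal rates); the root prior is the stationary (uniform)
distribution.  Likelihoods use Felsenstein's pruning algorithm.  Stochastic
maps are drawn by sampling node states from their conditional distributions
and then endpoint-conditioned histories along each branch (rejection
sampling with a uniformization fallback).
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

from .io import StrategyTable, normalize_label
from .tree import PhyloTree, RegimePainting, TreeError

__all__ = [
    "fit_mk_er",
    "mk_er_loglik",
    "mk_marginal_ancestral",
    "simmap_sample",
    "paint_from_hypothesis",
]


def _states_vector(tree: PhyloTree, tip_states) -> tuple[np.ndarray, tuple[str, str]]:
    if isinstance(tip_states, StrategyTable):
        mapping = tip_states.mapping
    else:
        mapping = {normalize_label(k): str(v) for k, v in dict(tip_states).items()}
    missing = [t for t in tree.tip_labels if t not in mapping]
    if missing:
        raise TreeError(f"tips without a state: {missing}")
    levels = tuple(sorted({mapping[t] for t in tree.tip_labels}))
    if len(levels) == 1:
        levels = (levels[0], levels[0] + "_alt")
    if len(levels) > 2:
        raise TreeError(f"binary trait expected, found levels {levels}")
    vec = np.array([levels.index(mapping[t]) for t in tree.tip_labels])
    return vec, levels


def _p_matrix(q: float, t: float) -> np.ndarray:
    e = np.exp(-2.0 * q * t)
    same = 0.5 * (1.0 + e)
    diff = 0.5 * (1.0 - e)
    return np.array([[same, diff], [diff, same]])


def _conditional_likelihoods(tree: PhyloTree, states: np.ndarray, q: float) -> dict[int, np.ndarray]:
    """Partial (downward) likelihoods L_v(s) for every node, by pruning."""
    L: dict[int, np.ndarray] = {}
    tip_of = {t.index: i for i, t in enumerate(tree.tips)}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(2)
            vec[states[tip_of[node.index]]] = 1.0
            L[node.index] = vec
        else:
            vec = np.ones(2)
            for child in node.children:
                P = _p_matrix(q, child.length)
                vec = vec * (P @ L[child.index])
            L[node.index] = vec
    return L


def mk_er_loglik(tree: PhyloTree, tip_states, q: float) -> float:
    """Log-likelihood of the equal-rates binary Mk model (uniform root prior)."""
    states, _ = _states_vector(tree, tip_states)
    L = _conditional_likelihoods(tree, states, q)
    lik = 0.5 * L[tree.root.index].sum()
    return float(np.log(lik)) if lik > 0 else -np.inf


def fit_mk_er(tree: PhyloTree, tip_states, q_max: float | None = None) -> tuple[float, float]:
    """Maximum-likelihood rate of the symmetric binary Markov chain.

    Returns ``(q_hat, logL)``.  Monomorphic tip states drive q to the zero
    boundary, which is reported (q ≈ 0, logL = log ½) rather than raised.
    """
    states, _ = _states_vector(tree, tip_states)
    if len(np.unique(states)) == 1:
        return 0.0, float(np.log(0.5))
    if q_max is None:
        q_max = 100.0 / max(tree.total_length() / (2 * tree.n_tips - 2), 1e-8)

    def nll(logq: float) -> float:
        return -mk_er_loglik(tree, tip_states, np.exp(logq))

    res = minimize_scalar(nll, bounds=(np.log(1e-8), np.log(q_max)), method="bounded",
                          options={"xatol": 1e-10})
    q_hat = float(np.exp(res.x))
    return q_hat, float(-res.fun)


def mk_marginal_ancestral(tree: PhyloTree, tip_states, q: float) -> dict[int, np.ndarray]:
    """Marginal ancestral state probabilities at every internal node.

    Standard up-down algorithm: downward partials from pruning combined with
    upward (outside-subtree) partials.
    """
    states, _ = _states_vector(tree, tip_states)
    L = _conditional_likelihoods(tree, states, q)
    up: dict[int, np.ndarray] = {tree.root.index: np.array([0.5, 0.5])}
    for node in tree.nodes:
        for child in node.children:
            sib = np.ones(2)
            for other in node.children:
                if other is child:
                    continue
                P = _p_matrix(q, other.length)
                sib = sib * (P @ L[other.index])
            msg = up[node.index] * sib
            P = _p_matrix(q, child.length)
            up[child.index] = P.T @ msg
    out: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        w = up[node.index] * L[node.index]
        out[node.index] = w / w.sum()
    return out


# ------------------------------------------------------------------ simmap

def _sample_path(a: int, b: int, t: float, q: float, rng: np.random.Generator,
                 max_rejects: int = 1000) -> list[tuple[float, int]]:
    """Endpoint-conditioned history on one branch: [(duration, state), ...].

    Rejection sampling of unconditioned chains first; after ``max_rejects``
    failures, uniformization (rate Λ = q gives the deterministic-flip
    uniformized chain, so the jump count only needs the right parity and
    Poisson weight).
    """
    if t <= 0:
        return [(t, b)] if a == b else [(0.0, a), (t, b)]
    if q <= 0:
        if a != b:
            raise TreeError("zero rate cannot connect differing endpoint states")
        return [(t, a)]
    for _ in range(max_rejects):
        times = []
        s = a
        pos = 0.0
        while True:
            wait = rng.exponential(1.0 / q)
            if pos + wait >= t:
                break
            pos += wait
            s = 1 - s
            times.append(pos)
        if s == b:
            return _times_to_segments(times, a, t)
    # uniformization: R = I + Q/q has zero diagonal, so every jump flips state
    lam = q * t
    parity = (a != b)
    ns = np.arange(0, max(20, int(lam + 10 * np.sqrt(lam) + 20)))
    weights = poisson.pmf(ns, lam)
    weights[(ns % 2 == 0) != (not parity)] = 0.0
    total = weights.sum()
    if total <= 0:
        n_jumps = 1 if parity else 0
    else:
        n_jumps = int(rng.choice(ns, p=weights / total))
    times = sorted(rng.uniform(0, t, size=n_jumps).tolist())
    return _times_to_segments(times, a, t)


def _times_to_segments(times: list[float], a: int, t: float) -> list[tuple[float, int]]:
    segs: list[tuple[float, int]] = []
    prev = 0.0
    s = a
    for tm in times:
        segs.append((tm - prev, s))
        prev = tm
        s = 1 - s
    segs.append((t - prev, s))
    return [(d, st) for d, st in segs if d > 0 or len(segs) == 1]


def simmap_sample(
    tree: PhyloTree,
    tip_states,
    q: float,
    n_maps: int = 10,
    seed: int | None = None,
) -> list[RegimePainting]:
    """Sample stochastic character maps consistent with the tip states.

    Node states are drawn from their conditional distributions (root from
    prior × partials, children given parents), then branch histories from the
    endpoint-conditioned chain.  Every returned painting reproduces the tip
    states exactly.
    """
    states, levels = _states_vector(tree, tip_states)
    rng = np.random.default_rng(seed)
    L = _conditional_likelihoods(tree, states, q)
    maps: list[RegimePainting] = []
    for _ in range(n_maps):
        node_state: dict[int, int] = {}
        w = 0.5 * L[tree.root.index]
        w = w / w.sum()
        node_state[tree.root.index] = int(rng.choice(2, p=w))
        for node in tree.nodes:
            for child in node.children:
                a = node_state[node.index]
                P = _p_matrix(q, child.length)
                w = P[a] * L[child.index]
                w = w / w.sum()
                node_state[child.index] = int(rng.choice(2, p=w))
        segments: dict[int, tuple[tuple[float, str], ...]] = {}
        for node in tree.nodes:
            if node.parent is None:
                continue
            a = node_state[node.parent.index]
            b = node_state[node.index]
            path = _sample_path(a, b, node.length, q, rng)
            segments[node.index] = tuple((d, levels[s]) for d, s in path)
        maps.append(
            RegimePainting(
                tree, segments, levels[node_state[tree.root.index]], levels
            )
        )
    return maps


# ------------------------------------------------- deterministic hypotheses

def paint_from_hypothesis(
    tree: PhyloTree,
    strategy,
    derived_level: str | None = None,
    stem_convention: str = "stem",
) -> RegimePainting:
    """Deterministic two-regime painting from a binary strategy table.

    The derived regime is painted on the smallest clade containing all taxa of
    the derived level; with ``stem_convention='stem'`` the shift sits at the
    base of that clade's stem branch (the whole stem is painted derived), with
    ``'crown'`` the stem stays ancestral.  The derived taxa must be
    monophyletic; otherwise a :class:`TreeError` instructs the caller to use
    stochastic mapping instead.
    """
    states, levels = _states_vector(tree, strategy)
    if len(set(states.tolist())) == 1:
        return RegimePainting.uniform(tree, levels[states[0]])
    if derived_level is None:
        # the minority level is taken as the derived (painted) regime
        counts = [int((states == i).sum()) for i in range(2)]
        derived = int(np.argmin(counts))
    else:
        if derived_level not in levels:
            raise TreeError(f"derived level {derived_level!r} not among {levels}")
        derived = levels.index(derived_level)
    ancestral = 1 - derived
    derived_taxa = [t for t, s in zip(tree.tip_labels, states) if s == derived]
    node = tree.mrca(derived_taxa)
    clade = set(tree.clade_tips(node))
    if clade != set(derived_taxa):
        raise TreeError(
            f"{levels[derived]!r} taxa are not monophyletic (clade adds "
            f"{sorted(clade - set(derived_taxa))}); use simmap_sample for this table"
        )
    inside = {node.index}
    stack = list(node.children)
    while stack:
        n = stack.pop()
        inside.add(n.index)
        stack.extend(n.children)
    if stem_convention not in {"stem", "crown"}:
        raise ValueError("stem_convention must be 'stem' or 'crown'")
    if stem_convention == "crown":
        inside.discard(node.index)
    segments = {
        n.index: ((n.length, levels[derived] if n.index in inside else levels[ancestral]),)
        for n in tree.nodes
        if n.parent is not None
    }
    return RegimePainting(tree, segments, levels[ancestral], levels)
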