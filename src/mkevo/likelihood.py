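"""Pruning-algorithm log-likelihood with root policies and node clamps.

Partial likelihoods are propagated tipward-to-rootward with per-node
rescaling (accumulated in log space) so large trees do not underflow. A
brute-force enumerator over internal-node state assignments serves as an
independent oracle for small trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .models import ModelSpec, transition_matrices
from .phylo import Phylogeny

__all__ = [
    "RootPolicy",
    "CladeClamp",
    "tip_partials",
    "prune_loglik",
    "brute_force_loglik",
    "joint_states",
]


@dataclass(frozen=True)
class RootPolicy:
    """Weighting of expanded states at the root.

    ``flat``: uniform over all k*R expanded states. ``fixed``: all mass on
    one observed state, split uniformly over its R hidden categories (the
    least-informative completion of a fixed observed root).
    """

    mode: str = "flat"  # "flat" | "fixed"
    state: int | None = None

    def prior(self, k: int, R: int) -> np.ndarray:
        m = k * R
        if self.mode == "flat":
            return np.full(m, 1.0 / m)
        if self.mode == "fixed":
            if self.state is None or not (0 <= self.state < k):
                raise ValueError(f"fixed root needs an observed state in [0, {k})")
            pi = np.zeros(m)
            for cat in range(R):
                pi[cat * k + self.state] = 1.0 / R
            return pi
        raise ValueError(f"unknown root mode {self.mode!r}")


@dataclass(frozen=True)
class CladeClamp:
    """Force an internal node's observed state (hidden categories stay free)."""

    node_id: int
    state: int

    def mask(self, k: int, R: int) -> np.ndarray:
        if not (0 <= self.state < k):
            raise ValueError(f"clamp state {self.state} outside alphabet of size {k}")
        m = np.zeros(k * R)
        for cat in range(R):
            m[cat * k + self.state] = 1.0
        return m


def tip_partials(
    tree: Phylogeny, states: dict[str, int | None], k: int, R: int
) -> dict[int, np.ndarray]:
    """Per-tip partial-likelihood vectors over the k*R expanded states.

    An observed state s puts 1 at (s, every category); missing data puts 1
    everywhere. Every tip label of the tree must appear in ``states``
    (use ``match_tree_and_traits`` to fill absences with None).
    """
    vecs: dict[int, np.ndarray] = {}
    for tip in tree.tips():
        if tip.label not in states:
            raise KeyError(f"no state for tip {tip.label!r}")
        s = states[tip.label]
        v = np.zeros(k * R)
        if s is None:
            v[:] = 1.0
        else:
            if not (0 <= s < k):
                raise ValueError(f"tip {tip.label!r}: state {s} outside alphabet")
            for cat in range(R):
                v[cat * k + s] = 1.0
        vecs[tip.id] = v
    return vecs


def joint_states(
    states1: dict[str, int | None], states2: dict[str, int | None]
) -> dict[str, int | None]:
    """Combine two binary traits into the 4-state coding (t1,t2) -> 2*t1 + t2.

    A species missing either trait is missing in the joint coding (full
    marginalization) rather than being dropped, so n stays constant.
    """
    out: dict[str, int | None] = {}
    for sp in states1:
        a, b = states1[sp], states2.get(sp)
        out[sp] = None if a is None or b is None else 2 * a + b
    return out


def _clamp_masks(
    tree: Phylogeny, clamps, k: int, R: int
) -> dict[int, np.ndarray]:
    masks: dict[int, np.ndarray] = {}
    for cl in clamps:
        nd = tree.nodes[cl.node_id]
        if nd.is_tip:
            raise ValueError(f"clamp on tip node {cl.node_id} ({nd.label!r})")
        m = cl.mask(k, R)
        masks[cl.node_id] = masks[cl.node_id] * m if cl.node_id in masks else m
    return masks


def prune_loglik(
    tree: Phylogeny,
    tips: dict[int, np.ndarray],
    Q: np.ndarray,
    root: RootPolicy,
    clamps=(),
    spec: ModelSpec | None = None,
    k: int | None = None,
    R: int = 1,
) -> float:
    """Felsenstein-pruning log-likelihood.

    Returns -inf (not an exception) when a clamp or impossible data zeroes
    the root vector, so model search over clamps stays total. ``spec`` or
    (``k``, ``R``) communicates the observed/hidden factorization of Q.
    """
    if spec is not None:
        k, R = spec.k, spec.R
    m = Q.shape[0]
    if k is None:
        k, R = m, 1
    if k * R != m:
        raise ValueError(f"Q dimension {m} != k*R = {k}*{R}")

    non_root = [nd for nd in tree.nodes if nd.id != tree.root_id]
    lengths = np.array([nd.length for nd in non_root])
    P = transition_matrices(Q, lengths)
    Pmap = {nd.id: P[i] for i, nd in enumerate(non_root)}
    masks = _clamp_masks(tree, clamps, k, R)

    partial: dict[int, np.ndarray] = {}
    logscale = 0.0
    for nd in tree.postorder():
        if nd.is_tip:
            partial[nd.id] = tips[nd.id]
            continue
        L = np.ones(m)
        for c in nd.children:
            L = L * (Pmap[c] @ partial[c])
        if nd.id in masks:
            L = L * masks[nd.id]
        mx = L.max()
        if mx <= 0.0:
            return -np.inf
        partial[nd.id] = L / mx
        logscale += np.log(mx)
    lik = float(root.prior(k, R) @ partial[tree.root_id])
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik) + logscale)


def brute_force_loglik(
    tree: Phylogeny,
    tips: dict[int, np.ndarray],
    Q: np.ndarray,
    root: RootPolicy,
    clamps=(),
    spec: ModelSpec | None = None,
    k: int | None = None,
    R: int = 1,
) -> float:
    """Exhaustive sum over every assignment of expanded states to internal nodes.

    Independent of the pruning recursion; only usable on small trees
    (<= 12 internal nodes and a bounded assignment count).
    """
    if spec is not None:
        k, R = spec.k, spec.R
    m = Q.shape[0]
    if k is None:
        k, R = m, 1
    internal = tree.internal_ids()
    if len(internal) > 12:
        raise ValueError(f"{len(internal)} internal nodes: brute force limited to 12")
    if m ** len(internal) > 4_000_000:
        raise ValueError("assignment space too large for brute force")

    non_root = [nd for nd in tree.nodes if nd.id != tree.root_id]
    lengths = np.array([nd.length for nd in non_root])
    P = transition_matrices(Q, lengths)
    Pmap = {nd.id: P[i] for i, nd in enumerate(non_root)}
    masks = _clamp_masks(tree, clamps, k, R)
    pos = {nid: j for j, nid in enumerate(internal)}

    assign = np.array(list(itertools.product(range(m), repeat=len(internal))), dtype=int)
    like = root.prior(k, R)[assign[:, pos[tree.root_id]]].astype(float)
    for nid, msk in masks.items():
        like = like * msk[assign[:, pos[nid]]]
    for nd in non_root:
        pa = assign[:, pos[nd.parent]]
        if nd.is_tip:
            emit = Pmap[nd.id] @ tips[nd.id]  # P(parent -> any tip-compatible state)
            like = like * emit[pa]
        else:
            like = like * Pmap[nd.id][pa, assign[:, pos[nd.id]]]
    total = float(like.sum())
    return float(np.log(total)) if total > 0.0 else -np.inf


def brute_force_marginals(
    tree: Phylogeny,
    tips: dict[int, np.ndarray],
    Q: np.ndarray,
    root: RootPolicy,
    clamps=(),
    spec: ModelSpec | None = None,
    k: int | None = None,
    R: int = 1,
) -> dict[int, np.ndarray]:
    """Exact expanded-state posteriors at internal nodes, by enumeration."""
    if spec is not None:
        k, R = spec.k, spec.R
    m = Q.shape[0]
    if k is None:
        k, R = m, 1
    internal = tree.internal_ids()
    if len(internal) > 12:
        raise ValueError(f"{len(internal)} internal nodes: brute force limited to 12")

    non_root = [nd for nd in tree.nodes if nd.id != tree.root_id]
    lengths = np.array([nd.length for nd in non_root])
    P = transition_matrices(Q, lengths)
    Pmap = {nd.id: P[i] for i, nd in enumerate(non_root)}
    masks = _clamp_masks(tree, clamps, k, R)
    pos = {nid: j for j, nid in enumerate(internal)}

    assign = np.array(list(itertools.product(range(m), repeat=len(internal))), dtype=int)
    like = root.prior(k, R)[assign[:, pos[tree.root_id]]].astype(float)
    for nid, msk in masks.items():
        like = like * msk[assign[:, pos[nid]]]
    for nd in non_root:
        pa = assign[:, pos[nd.parent]]
        if nd.is_tip:
            emit = Pmap[nd.id] @ tips[nd.id]
            like = like * emit[pa]
        else:
            like = like * Pmap[nd.id][pa, assign[:, pos[nd.id]]]
    total = like.sum()
    if total <= 0.0:
        raise ValueError("zero likelihood: marginals undefined")
    out: dict[int, np.ndarray] = {}
    for nid in internal:
        probs = np.array([like[assign[:, pos[nid]] == s].sum() for s in range(m)])
        out[nid] = probs / total
    return out
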