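"""Marginal ancestral-state probabilities and transition counting.

The marginal posterior at a node combines the below-node partial
likelihoods (tipward pass) with the likelihood of everything outside the
node's subtree (rootward pass). Hidden-category mass is summed into
observed states before reporting; a verbose mode exposes the expanded
marginals.

Transition counting is MAP-state parsimony over the marginal map with an
explicit ambiguity band reported as a [min, max] range, because point
counts hide reconstruction uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import RootPolicy, _clamp_masks
from .models import ModelSpec, transition_matrices
from .phylo import Phylogeny

__all__ = ["MarginalMap", "TransitionTally", "marginal_reconstruct", "count_transitions"]


@dataclass
class MarginalMap:
    """Per-node posterior over observed states, plus MAP calls."""

    k: int
    R: int
    probs: dict[int, np.ndarray]  # node id -> length-k observed-state posterior
    expanded: dict[int, np.ndarray]  # node id -> length-k*R expanded posterior
    map_state: dict[int, int]
    map_prob: dict[int, float]

    def internal_ids(self, tree: Phylogeny) -> list[int]:
        return [i for i in self.probs if not tree.nodes[i].is_tip]

    def to_csv(self, tree: Phylogeny) -> str:
        header = ["node_id", "label"] + [f"p_state{s}" for s in range(self.k)]
        header += ["map_state", "map_prob"]
        lines = [",".join(header)]
        for nid in sorted(self.probs):
            nd = tree.nodes[nid]
            cells = [str(nid), nd.label or ""]
            cells += [f"{p:.10g}" for p in self.probs[nid]]
            cells += [str(self.map_state[nid]), f"{self.map_prob[nid]:.10g}"]
            lines.append(",".join(cells))
        return "\n".join(lines) + "\n"


def marginal_reconstruct(
    tree: Phylogeny,
    tips: dict[int, np.ndarray],
    Q: np.ndarray,
    root: RootPolicy,
    clamps=(),
    spec: ModelSpec | None = None,
    k: int | None = None,
    R: int = 1,
) -> MarginalMap:
    """Exact marginal posteriors P(state at node | tips, Q, root) at every node.

    Two passes: a postorder pass accumulates below-node partials, a preorder
    pass pushes outside-subtree likelihoods down. Per-node rescaling factors
    cancel in the final per-node normalization.
    """
    if spec is not None:
        k, R = spec.k, spec.R
    m = Q.shape[0]
    if k is None:
        k, R = m, 1

    non_root = [nd for nd in tree.nodes if nd.id != tree.root_id]
    lengths = np.array([nd.length for nd in non_root])
    P = transition_matrices(Q, lengths)
    Pmap = {nd.id: P[i] for i, nd in enumerate(non_root)}
    masks = _clamp_masks(tree, clamps, k, R)

    # tipward pass: below[v] = (masked) product over children of P_c @ below[c]
    below: dict[int, np.ndarray] = {}
    childmsg: dict[int, np.ndarray] = {}  # child id -> P_c @ below[c]
    for nd in tree.postorder():
        if nd.is_tip:
            below[nd.id] = tips[nd.id]
        else:
            L = np.ones(m)
            for c in nd.children:
                msg = Pmap[c] @ below[c]
                childmsg[c] = msg
                L = L * msg
            if nd.id in masks:
                L = L * masks[nd.id]
            mx = L.max()
            if mx <= 0.0:
                raise ValueError("zero likelihood (clamp incompatible with data): marginals undefined")
            below[nd.id] = L / mx

    # rootward pass: above[v] = likelihood of data outside v's subtree per state
    above: dict[int, np.ndarray] = {tree.root_id: root.prior(k, R)}
    for nd in tree.preorder():
        if nd.is_tip:
            continue
        base = above[nd.id]
        if nd.id in masks:
            base = base * masks[nd.id]
        for c in nd.children:
            sib = base.copy()
            for b in nd.children:
                if b != c:
                    sib = sib * childmsg[b]
            vec = Pmap[c].T @ sib
            mx = vec.max()
            above[c] = vec / mx if mx > 0 else vec

    probs: dict[int, np.ndarray] = {}
    expanded: dict[int, np.ndarray] = {}
    map_state: dict[int, int] = {}
    map_prob: dict[int, float] = {}
    for nd in tree.nodes:
        post = above[nd.id] * below[nd.id]
        tot = post.sum()
        if tot <= 0.0:
            raise ValueError(f"zero posterior mass at node {nd.id}")
        post = post / tot
        obs = post.reshape(R, k).sum(axis=0)
        expanded[nd.id] = post
        probs[nd.id] = obs
        map_state[nd.id] = int(np.argmax(obs))
        map_prob[nd.id] = float(obs.max())
    return MarginalMap(k=k, R=R, probs=probs, expanded=expanded, map_state=map_state, map_prob=map_prob)


@dataclass
class TransitionTally:
    """Counts of MAP parent->child state changes, with an ambiguity range."""

    counts: dict[tuple[int, int], tuple[int, int]]  # (from, to) -> (min, max)
    total: tuple[int, int]
    branches: list[dict] = field(default_factory=list)
    threshold: float = 0.7

    def range_for(self, from_state: int, to_state: int) -> tuple[int, int]:
        return self.counts.get((from_state, to_state), (0, 0))

    def to_csv(self) -> str:
        lines = ["parent_id,child_id,from_state,to_state,ambiguous"]
        for b in self.branches:
            lines.append(
                f"{b['parent_id']},{b['child_id']},{b['from_state']},{b['to_state']},{int(b['ambiguous'])}"
            )
        return "\n".join(lines) + "\n"


def count_transitions(
    marginals: MarginalMap, tree: Phylogeny, map_threshold: float = 0.7
) -> TransitionTally:
    """Tally branches on which the MAP observed state changes parent->child.

    Branches touching a node whose MAP probability is below ``map_threshold``
    (or exactly tied) count only toward the upper bound of the [min, max]
    range; unambiguous changes count toward both.
    """
    if not (0.5 < map_threshold <= 1.0):
        raise ValueError("map_threshold must lie in (0.5, 1]")
    ambiguous_node = {
        nid: (marginals.map_prob[nid] < map_threshold)
        or np.isclose(marginals.map_prob[nid], 1.0 / marginals.k)
        for nid in marginals.map_state
    }
    counts: dict[tuple[int, int], list[int]] = {}
    branches: list[dict] = []
    tot_min = tot_max = 0
    for nd in tree.nodes:
        if nd.parent is None:
            continue
        a, b = marginals.map_state[nd.parent], marginals.map_state[nd.id]
        if a == b:
            continue
        amb = ambiguous_node[nd.parent] or ambiguous_node[nd.id]
        lohi = counts.setdefault((a, b), [0, 0])
        lohi[1] += 1
        tot_max += 1
        if not amb:
            lohi[0] += 1
            tot_min += 1
        branches.append(
            {"parent_id": nd.parent, "child_id": nd.id, "from_state": a, "to_state": b, "ambiguous": amb}
        )
    return TransitionTally(
        counts={kk: (v[0], v[1]) for kk, v in counts.items()},
        total=(tot_min, tot_max),
        branches=branches,
        threshold=map_threshold,
    )
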