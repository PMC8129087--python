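"""Random small problem instances shared by oracle-equivalence tests."""

from __future__ import annotations

import numpy as np

from mkevo import CladeClamp, RootPolicy, build_q, make_spec, tip_partials
from mkevo.phylo import Node, Phylogeny

CONFIGS = [  # (k, R, family, switch)
    (2, 1, "ARD", "distinct"),
    (2, 2, "ER/ARD", "distinct"),
    (4, 1, "ARD_loss", "distinct"),
    (4, 2, "ER/ER", "distinct"),
    (2, 1, "ER", "distinct"),
    (4, 2, "ER/ARD", "shared"),
]


def random_topology(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random rooted tree over n_tips labels, polytomies included."""
    labels = [f"t{i}" for i in range(1, n_tips + 1)]
    nodes: list[Node] = []

    def build(labs: list[str], parent: int | None) -> int:
        nid = len(nodes)
        length = 0.0 if parent is None else float(rng.uniform(0.05, 3.0))
        if len(labs) == 1:
            nodes.append(Node(id=nid, parent=parent, length=length, label=labs[0]))
            return nid
        nodes.append(Node(id=nid, parent=parent, length=length))
        n_groups = int(rng.integers(2, min(len(labs), 3) + 1))
        order = list(rng.permutation(len(labs)))
        cuts = sorted(rng.choice(range(1, len(labs)), size=n_groups - 1, replace=False))
        groups, prev = [], 0
        for c in list(cuts) + [len(labs)]:
            groups.append([labs[order[j]] for j in range(prev, c)])
            prev = c
        for g in groups:
            cid = build(g, nid)
            nodes[nid].children.append(cid)
        return nid

    build(labels, None)
    return Phylogeny(nodes, root_id=0)


def random_instance(seed: int, with_clamps: bool = True, max_tips: int = 6) -> dict:
    """A random tree + model + tip data, optionally with a clamp."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_tips + 1))
    tree = random_topology(rng, n)
    k, R, fam, sw = CONFIGS[seed % len(CONFIGS)]
    spec = make_spec(fam, k=k, R=R, category_switch=sw)
    params = rng.uniform(0.05, 1.2, size=spec.k_free)
    Q = build_q(spec, params)
    states = {
        lab: (None if rng.random() < 0.2 else int(rng.integers(k)))
        for lab in tree.tip_labels()
    }
    tips = tip_partials(tree, states, k, R)
    root = RootPolicy("flat") if seed % 2 else RootPolicy("fixed", int(rng.integers(k)))
    clamps = ()
    if with_clamps and seed % 3 == 0:
        internals = [i for i in tree.internal_ids() if i != tree.root_id] or tree.internal_ids()
        nid = internals[int(rng.integers(len(internals)))]
        clamps = (CladeClamp(node_id=nid, state=int(rng.integers(k))),)
    return {
        "tree": tree,
        "states": states,
        "tips": tips,
        "spec": spec,
        "Q": Q,
        "root": root,
        "clamps": clamps,
    }
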