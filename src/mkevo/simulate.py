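"""Synthetic trees and trait histories with recorded ground truth.

Pure-birth (Yule) trees rescaled to a target height emulate a chronogram;
traits evolve along branches by Gillespie simulation under an arbitrary
generator, recording every event (including hidden-category switches) in
absolute node-time coordinates (root = 0, increasing tipward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ModelSpec, build_q
from .phylo import Node, Phylogeny, TraitTable

__all__ = ["SimResult", "simulate_tree", "simulate_traits", "make_paper_like_fixture"]


def simulate_tree(
    n_tips: int, height: float, birth_rate: float = 1.0, seed: int = 1
) -> Phylogeny:
    """Yule tree grown to ``n_tips`` then rescaled so every tip depth = height.

    The root is the first split (two lineages at time 0), so the tree is
    ultrametric with root-to-tip distance exactly ``height``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if height <= 0 or birth_rate <= 0:
        raise ValueError("height and birth_rate must be positive")
    rng = np.random.default_rng(seed)

    # each active lineage: (parent split-event index, birth time)
    split_time: list[float] = [0.0]  # per split event; event 0 is the root
    split_parent: list[int | None] = [None]
    active: list[tuple[int, float]] = [(0, 0.0), (0, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        parent_event, _ = active.pop(int(i))
        ev = len(split_time)
        split_time.append(t)
        split_parent.append(parent_event)
        active.append((ev, t))
        active.append((ev, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    scale = height / t_end

    nodes: list[Node] = []
    ev_to_node: dict[int, int] = {}
    for ev in range(len(split_time)):
        nid = len(nodes)
        ev_to_node[ev] = nid
        pev = split_parent[ev]
        if pev is None:
            nodes.append(Node(id=nid, parent=None, length=0.0))
        else:
            length = (split_time[ev] - split_time[pev]) * scale
            pid = ev_to_node[pev]
            nodes.append(Node(id=nid, parent=pid, length=length))
            nodes[pid].children.append(nid)
    for j, (pev, btime) in enumerate(active):
        nid = len(nodes)
        pid = ev_to_node[pev]
        nodes.append(
            Node(id=nid, parent=pid, length=(t_end - split_time[pev]) * scale, label=f"t{j + 1}")
        )
        nodes[pid].children.append(nid)
    return Phylogeny(nodes, root_id=0)


@dataclass
class SimResult:
    """Simulated tip states plus the true branch-by-branch change history."""

    tree: Phylogeny
    spec: ModelSpec
    tip_states: dict[str, int]  # observed states at tips
    tip_expanded: dict[str, int]  # expanded (category-aware) states at tips
    histories: dict[int, list[tuple[float, int, int]]]  # child node id -> events
    counts: dict[tuple[int, int], int] = field(default_factory=dict)  # expanded
    obs_counts: dict[tuple[int, int], int] = field(default_factory=dict)  # category-free

    def n_events(self) -> int:
        return sum(self.counts.values())

    def to_trait_table(self, character: str = "trait") -> TraitTable:
        return TraitTable(
            characters=[character],
            states={sp: (s,) for sp, s in self.tip_states.items()},
        )


def simulate_traits(
    tree: Phylogeny,
    spec: ModelSpec,
    params,
    root_state: int = 0,
    root_category: int = 0,
    seed: int = 1,
) -> SimResult:
    """Gillespie simulation of the CTMC along every branch.

    Waiting times are exponential with rate -Q[s][s]; jumps go to s' with
    probability Q[s][s']/(-Q[s][s]). Event times are absolute (root = 0).
    Deterministic given ``seed``.
    """
    Q = build_q(spec, params)
    k, R = spec.k, spec.R
    if not (0 <= root_state < k) or not (0 <= root_category < R):
        raise ValueError("root state/category outside the model's alphabet")
    rng = np.random.default_rng(seed)
    depth = tree.node_depths()

    state_at: dict[int, int] = {tree.root_id: root_category * k + root_state}
    histories: dict[int, list[tuple[float, int, int]]] = {}
    counts: dict[tuple[int, int], int] = {}
    obs_counts: dict[tuple[int, int], int] = {}
    for nd in tree.preorder():
        if nd.id == tree.root_id:
            continue
        s = state_at[nd.parent]
        t0, t1 = depth[nd.parent], depth[nd.id]
        t = t0
        events: list[tuple[float, int, int]] = []
        while True:
            out = -Q[s, s]
            if out <= 0.0:
                break
            t += rng.exponential(1.0 / out)
            if t >= t1:
                break
            p = Q[s].clip(min=0.0)
            p[s] = 0.0
            p = p / p.sum()
            s2 = int(rng.choice(len(p), p=p))
            events.append((t, s, s2))
            counts[(s, s2)] = counts.get((s, s2), 0) + 1
            if s % k != s2 % k:
                key = (s % k, s2 % k)
                obs_counts[key] = obs_counts.get(key, 0) + 1
            s = s2
        histories[nd.id] = events
        state_at[nd.id] = s
    tip_states = {nd.label: state_at[nd.id] % k for nd in tree.tips()}
    tip_expanded = {nd.label: state_at[nd.id] for nd in tree.tips()}
    return SimResult(
        tree=tree,
        spec=spec,
        tip_states=tip_states,
        tip_expanded=tip_expanded,
        histories=histories,
        counts=counts,
        obs_counts=obs_counts,
    )


def make_paper_like_fixture(seed: int = 1) -> tuple[Phylogeny, TraitTable, TraitTable]:
    """A 292-tip, height-200 chronogram with two binary traits.

    Trait "gland" is rare (~18% present, 6 species missing) and trait
    "habitat" has ~25% state 1; both are generated under a two-category
    hidden-rate model so the fixture stresses the full pipeline. The tree
    and each trait use derived seeds so any piece can be regenerated alone.
    """
    tree = simulate_tree(292, 200.0, birth_rate=0.025, seed=seed)
    hidden = _hidden_er_er()

    def draw(target_lo: float, target_hi: float, base_seed: int) -> dict[str, int]:
        for trial in range(200):
            sim = simulate_traits(
                tree,
                hidden,
                # slow category, fast category, switch rates
                params=[0.0006, 0.02, 0.004, 0.004],
                root_state=0,
                root_category=0,
                seed=base_seed + 1000 * trial,
            )
            frac = np.mean([s for s in sim.tip_states.values()])
            if target_lo <= frac <= target_hi:
                return sim.tip_states
        raise RuntimeError("could not hit target state frequency")

    gland = draw(0.10, 0.26, seed + 1)
    habitat = draw(0.15, 0.35, seed + 2)

    rng = np.random.default_rng(seed + 3)
    missing = rng.choice(sorted(gland), size=6, replace=False)
    gland_states: dict[str, tuple[int | None, ...]] = {
        sp: ((None,) if sp in set(missing) else (gland[sp],)) for sp in sorted(gland)
    }
    tt_gland = TraitTable(characters=["gland"], states=gland_states)
    tt_hab = TraitTable(
        characters=["habitat"], states={sp: (habitat[sp],) for sp in sorted(habitat)}
    )
    return tree, tt_gland, tt_hab


def _hidden_er_er() -> ModelSpec:
    from .models import make_spec

    return make_spec("ER/ER", k=2, R=2, category_switch="distinct")
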