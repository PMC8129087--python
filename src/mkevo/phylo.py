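"""Trees and trait tables.

Newick reading/writing (via dendropy), CSV trait tables, and the tree
queries (mrca, pruning, traversal orders) used by every downstream stage.

Branch lengths are interpreted as absolute time; no unit conversion is
applied anywhere. Polytomies are retained. Zero-length branches are legal.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd

__all__ = [
    "NewickError",
    "TraitTableError",
    "Node",
    "Phylogeny",
    "TraitTable",
    "read_newick",
    "write_newick",
    "read_trait_table",
    "match_tree_and_traits",
]


class NewickError(ValueError):
    """Malformed Newick input or a tree unusable as a chronogram."""


class TraitTableError(ValueError):
    """Malformed or inconsistent trait table."""


@dataclass
class Node:
    id: int
    parent: int | None
    children: list[int] = field(default_factory=list)
    length: float = 0.0  # branch length to parent; 0.0 (ignored) for the root
    label: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with branch lengths in time units.

    Nodes are stored in a flat list indexed by id; the root always has
    id 0 and ids follow a preorder of the input. Invariants (single root,
    finite non-negative lengths, unique non-empty tip labels, connected)
    are checked on construction.
    """

    def __init__(self, nodes: Sequence[Node], root_id: int = 0):
        self.nodes = list(nodes)
        self.root_id = root_id
        self._validate()

    # -- construction checks -------------------------------------------------

    def _validate(self) -> None:
        roots = [nd.id for nd in self.nodes if nd.parent is None]
        if roots != [self.root_id]:
            raise ValueError(f"expected exactly one parentless node {self.root_id}, got {roots}")
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise ValueError("cycle detected in tree")
            seen.add(i)
            stack.extend(self.nodes[i].children)
        if len(seen) != len(self.nodes):
            raise ValueError("tree is not connected: unreachable nodes present")
        labels = []
        for nd in self.nodes:
            if nd.id != self.root_id:
                if not math.isfinite(nd.length) or nd.length < 0:
                    raise ValueError(f"node {nd.id}: branch length must be finite and >= 0")
            if nd.is_tip:
                if not nd.label:
                    raise ValueError(f"tip node {nd.id} has an empty label")
                labels.append(nd.label)
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")

    # -- basic queries --------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_tip)

    @property
    def root(self) -> Node:
        return self.nodes[self.root_id]

    def tips(self) -> list[Node]:
        return [nd for nd in self.nodes if nd.is_tip]

    def tip_labels(self) -> list[str]:
        return [nd.label for nd in self.tips()]  # type: ignore[misc]

    def internal_ids(self) -> list[int]:
        return [nd.id for nd in self.nodes if not nd.is_tip]

    def node_by_label(self, label: str) -> Node:
        for nd in self.nodes:
            if nd.label == label:
                return nd
        raise KeyError(f"no node labelled {label!r}")

    def postorder(self) -> Iterator[Node]:
        """Children before parents."""
        out: list[int] = []
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.nodes[i].children)
        for i in reversed(out):
            yield self.nodes[i]

    def preorder(self) -> Iterator[Node]:
        """Parents before children."""
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            yield self.nodes[i]
            stack.extend(reversed(self.nodes[i].children))

    def total_branch_length(self) -> float:
        return sum(nd.length for nd in self.nodes if nd.id != self.root_id)

    def node_depths(self) -> dict[int, float]:
        """Time from the root to each node (root = 0, increasing tipward)."""
        depth = {self.root_id: 0.0}
        for nd in self.preorder():
            if nd.id != self.root_id:
                depth[nd.id] = depth[nd.parent] + nd.length  # type: ignore[index]
        return depth

    def descendant_tips(self, node_id: int) -> list[Node]:
        out = []
        stack = [node_id]
        while stack:
            i = stack.pop()
            nd = self.nodes[i]
            if nd.is_tip:
                out.append(nd)
            stack.extend(nd.children)
        return out

    # -- mrca and pruning -----------------------------------------------------

    def mrca(self, labels: Iterable[str]) -> int:
        """Id of the most recent common ancestor of the named tips."""
        labels = list(labels)
        if not labels:
            raise ValueError("mrca of an empty tip set is undefined")
        by_label = {nd.label: nd.id for nd in self.tips()}
        for lab in labels:
            if lab not in by_label:
                raise KeyError(f"unknown tip label {lab!r}")
        # path of the first tip to the root, tip-first
        path: list[int] = []
        i: int | None = by_label[labels[0]]
        while i is not None:
            path.append(i)
            i = self.nodes[i].parent
        rank = {nid: r for r, nid in enumerate(path)}
        best = 0
        for lab in labels[1:]:
            j: int | None = by_label[lab]
            while j is not None and j not in rank:
                j = self.nodes[j].parent
            assert j is not None  # root is always shared
            best = max(best, rank[j])
        return path[best]

    def prune_to_clade(self, node_id: int) -> "Phylogeny":
        """Subtree rooted at an internal node; branch lengths preserved."""
        nd = self.nodes[node_id]
        if nd.is_tip:
            raise ValueError(f"cannot prune to a tip (node {node_id})")
        remap: dict[int, int] = {}
        new_nodes: list[Node] = []
        stack = [(node_id, None)]
        # preorder copy so the new root gets id 0
        order: list[int] = []
        s = [node_id]
        while s:
            i = s.pop()
            order.append(i)
            s.extend(reversed(self.nodes[i].children))
        for i in order:
            remap[i] = len(new_nodes)
            old = self.nodes[i]
            parent = None if i == node_id else remap[old.parent]  # type: ignore[index]
            new_nodes.append(
                Node(
                    id=remap[i],
                    parent=parent,
                    children=[],
                    length=0.0 if i == node_id else old.length,
                    label=old.label,
                )
            )
        for i in order:
            if i != node_id:
                new_nodes[remap[self.nodes[i].parent]].children.append(remap[i])  # type: ignore[index]
        return Phylogeny(new_nodes, root_id=0)

    # -- conversion -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:  # structural, exact lengths
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __repr__(self) -> str:
        return f"<Phylogeny: {self.n_tips} tips, {len(self.nodes)} nodes>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def read_newick(text: str, normalize_underscores: bool = False) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths.

    Every non-root edge must carry a branch length (a time-calibrated tree
    is required); polytomies are preserved. With ``normalize_underscores``
    unquoted underscores in labels are mapped to spaces (off by default:
    silent conversion causes label-mismatch bugs).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=not normalize_underscores,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise NewickError(f"Newick parse error: {exc}") from exc

    nodes: list[Node] = []
    remap: dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        nid = len(nodes)
        remap[id(dnode)] = nid
        parent = None if dnode.parent_node is None else remap[id(dnode.parent_node)]
        label = None
        if dnode.taxon is not None and dnode.taxon.label is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        if label is not None:
            label = label.strip().strip("'\"").strip()
            if not label:
                label = None
        length = dnode.edge.length
        if parent is None:
            length = 0.0
        elif length is None:
            raise NewickError(
                f"missing branch length on the edge above node "
                f"{label or nid!r}: a time-calibrated tree is required"
            )
        nodes.append(Node(id=nid, parent=parent, length=float(length), label=label))
    for nd in nodes:
        if nd.parent is not None:
            nodes[nd.parent].children.append(nd.id)
    try:
        return Phylogeny(nodes, root_id=0)
    except ValueError as exc:
        raise NewickError(str(exc)) from exc


_NEEDS_QUOTES = set(" ()[]{}:;,'\"\t\n")


def _fmt_label(label: str) -> str:
    if any(c in _NEEDS_QUOTES for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    return repr(float(x))  # shortest exact round-trip representation


def write_newick(tree: Phylogeny) -> str:
    """Serialize so that ``read_newick`` reproduces topology, labels and lengths."""

    def rec(i: int) -> str:
        nd = tree.nodes[i]
        if nd.is_tip:
            s = _fmt_label(nd.label)  # type: ignore[arg-type]
        else:
            s = "(" + ",".join(rec(c) for c in nd.children) + ")"
            if nd.label:
                s += _fmt_label(nd.label)
        if i != tree.root_id:
            s += ":" + _fmt_length(nd.length)
        return s

    return rec(tree.root_id) + ";"


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Per-species binary states; ``None`` encodes missing data."""

    characters: list[str]
    states: dict[str, tuple[int | None, ...]]  # species -> state per character

    @property
    def species(self) -> list[str]:
        return list(self.states)

    def n_missing(self, character: str) -> int:
        ci = self.characters.index(character)
        return sum(1 for v in self.states.values() if v[ci] is None)

    def column(self, character: str) -> dict[str, int | None]:
        ci = self.characters.index(character)
        return {sp: v[ci] for sp, v in self.states.items()}

    def to_csv(self, missing_code: str = "?") -> str:
        rows = ["species," + ",".join(self.characters)]
        for sp, vals in self.states.items():
            cells = [missing_code if v is None else str(v) for v in vals]
            name = f'"{sp}"' if "," in sp else sp
            rows.append(name + "," + ",".join(cells))
        return "\n".join(rows) + "\n"


def read_trait_table(
    text: str,
    missing_code: str = "?",
    alphabet: tuple[str, ...] = ("0", "1"),
) -> TraitTable:
    """Parse a CSV with a species column followed by >=1 character columns.

    States must come from ``alphabet`` or equal ``missing_code``; an empty
    cell is an error, not a silent missing value.
    """
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise TraitTableError("need a species column plus at least one character column")
    species_col = df.columns[0]
    characters = [str(c) for c in df.columns[1:]]
    states: dict[str, tuple[int | None, ...]] = {}
    for ridx, row in df.iterrows():
        sp = str(row[species_col]).strip().strip("'\"").strip()
        if not sp:
            raise TraitTableError(f"row {ridx + 2}: empty species label")
        if sp in states:
            raise TraitTableError(f"duplicate species {sp!r}")
        vals: list[int | None] = []
        for ch in characters:
            cell = str(row[ch]).strip()
            if cell == missing_code:
                vals.append(None)
            elif cell in alphabet:
                vals.append(alphabet.index(cell))
            elif cell == "":
                raise TraitTableError(
                    f"row {ridx + 2} ({sp!r}), character {ch!r}: empty state cell "
                    f"(use {missing_code!r} for missing data)"
                )
            else:
                raise TraitTableError(
                    f"row {ridx + 2} ({sp!r}), character {ch!r}: state {cell!r} "
                    f"not in alphabet {alphabet} or missing code {missing_code!r}"
                )
        states[sp] = tuple(vals)
    return TraitTable(characters=characters, states=states)


def match_tree_and_traits(
    tree: Phylogeny, traits: TraitTable, character: str | None = None
) -> tuple[dict[str, int | None], dict]:
    """Align tip labels with trait rows.

    Returns ``(states, report)`` where ``states`` maps every tip label to a
    state or None. Tips absent from the table become missing data; table
    rows absent from the tree are dropped. Both are listed in the report.
    """
    character = character or traits.characters[0]
    col = traits.column(character)
    tips = set(tree.tip_labels())
    common = tips & set(col)
    if not common:
        raise TraitTableError("no overlap between tree tip labels and trait table species")
    states: dict[str, int | None] = {}
    tips_without = sorted(tips - set(col))
    dropped = sorted(set(col) - tips)
    for lab in tree.tip_labels():
        states[lab] = col.get(lab)  # None when absent => missing data
    report = {
        "character": character,
        "n_matched": len(common),
        "tips_without_traits": tips_without,
        "dropped_rows": dropped,
    }
    return states, report
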