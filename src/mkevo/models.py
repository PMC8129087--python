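"""Declarative construction of constrained and hidden-rate generator matrices.

A ``ModelSpec`` maps every allowed off-diagonal cell of the (k*R)x(k*R)
generator either to a free-parameter index or to a structural zero. State
indexing is category-major; within a category the observed states appear
in declared order. For joint binary traits (k=4) the observed states are
ordered (0,0),(0,1),(1,0),(1,1) with trait1 = habitat-like, trait2 =
gland-like, and cells representing simultaneous change of both traits are
structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "ModelSpec",
    "make_spec",
    "custom_spec",
    "build_q",
    "transition_probabilities",
    "transition_matrices",
]

Cell = tuple[int, int]


def allowed_cells(k: int) -> list[Cell]:
    """Off-diagonal cells a single-category generator may populate."""
    if k == 2:
        return [(0, 1), (1, 0)]
    if k == 4:
        # single-trait changes only; (0,0)<->(1,1) and (0,1)<->(1,0) are zero
        return [(0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2)]
    raise ValueError(f"unsupported alphabet size k={k} (expected 2 or 4)")


def _family_keys(family: str, k: int) -> dict[Cell, str]:
    """Map each allowed cell to a parameter key for one named rate family."""
    cells = allowed_cells(k)
    if family == "ER":
        return {c: "rate" for c in cells}
    if family == "ARD":
        return {c: f"q{c[0]}{c[1]}" for c in cells}
    if family == "IND":
        if k != 4:
            raise ValueError("IND is a joint-trait (k=4) family")
        # one rate per trait-direction, shared across the other trait's states
        return {
            (0, 1): "t2_gain", (2, 3): "t2_gain",
            (1, 0): "t2_loss", (3, 2): "t2_loss",
            (0, 2): "t1_gain", (1, 3): "t1_gain",
            (2, 0): "t1_loss", (3, 1): "t1_loss",
        }
    if family == "ARD_loss":
        if k != 4:
            raise ValueError("ARD_loss is a joint-trait (k=4) family")
        keys = {c: f"q{c[0]}{c[1]}" for c in cells}
        keys[(1, 0)] = "gland_loss"  # (0,1)->(0,0) tied to ...
        keys[(3, 2)] = "gland_loss"  # ... (1,1)->(1,0)
        return keys
    raise ValueError(f"unknown rate family {family!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Parameter-sharing map for a (possibly hidden-rate) generator."""

    name: str
    k: int  # observed-state alphabet size
    R: int  # number of hidden rate categories
    param_index: np.ndarray  # (k*R, k*R) int; -1 = structural zero / diagonal
    param_names: tuple[str, ...] = field(default=())

    @property
    def m(self) -> int:
        return self.k * self.R

    @property
    def k_free(self) -> int:
        idx = self.param_index[self.param_index >= 0]
        return int(idx.max()) + 1 if idx.size else 0

    def cells_of(self, param: int) -> list[Cell]:
        r, c = np.nonzero(self.param_index == param)
        return list(zip(r.tolist(), c.tolist()))

    def __post_init__(self):
        pi = self.param_index
        if pi.shape != (self.m, self.m):
            raise ValueError("param_index has wrong shape")
        if np.any(np.diag(pi) != -1):
            raise ValueError("diagonal cells must be -1")
        used = sorted(set(pi[pi >= 0].tolist()))
        if used != list(range(len(used))):
            raise ValueError("parameter indices must be 0..k_free-1 without gaps")


def _assemble(
    name: str,
    k: int,
    R: int,
    category_families: tuple[str, ...],
    category_switch: str,
) -> ModelSpec:
    m = k * R
    pi = -np.ones((m, m), dtype=int)
    key_to_idx: dict[str, int] = {}
    names: list[str] = []

    def idx_for(key: str) -> int:
        if key not in key_to_idx:
            key_to_idx[key] = len(names)
            names.append(key)
        return key_to_idx[key]

    for cat, fam in enumerate(category_families):
        off = cat * k
        for (a, b), key in _family_keys(fam, k).items():
            pi[off + a, off + b] = idx_for(f"R{cat + 1}.{key}")
    if R == 2:
        if category_switch == "distinct":
            keys = ("switch.R1R2", "switch.R2R1")
        elif category_switch == "shared":
            keys = ("switch", "switch")
        else:
            raise ValueError("category_switch must be 'distinct' or 'shared'")
        for s in range(k):
            pi[s, k + s] = idx_for(keys[0])
            pi[k + s, s] = idx_for(keys[1])
    return ModelSpec(name=name, k=k, R=R, param_index=pi, param_names=tuple(names))


def make_spec(
    family: str,
    k: int = 2,
    R: int = 1,
    category_families: tuple[str, str] | None = None,
    category_switch: str = "distinct",
) -> ModelSpec:
    """Build a named model family.

    ``family`` is one of ER, ARD, IND, ARD_loss for R=1, or a pair such as
    "ER/ARD" (equivalently via ``category_families``) for R=2. Category
    switching is observed-state-independent: one R1->R2 and one R2->R1 rate
    apply to every observed state ('distinct'), or a single rate covers both
    directions ('shared').
    """
    if k not in (2, 4):
        raise ValueError(f"unsupported k={k}")
    if R not in (1, 2):
        raise ValueError(f"unsupported R={R}")
    if R == 1:
        if "/" in family:
            raise ValueError("hidden families require R=2")
        return _assemble(family, k, 1, (family,), category_switch)
    if category_families is None:
        if "/" not in family:
            raise ValueError("R=2 requires category_families or a 'F1/F2' name")
        parts = family.split("/")
        if len(parts) != 2:
            raise ValueError(f"bad hidden family name {family!r}")
        category_families = (parts[0], parts[1])
    name = family if "/" in family else "/".join(category_families)
    return _assemble(name, k, 2, category_families, category_switch)


def custom_spec(
    k: int,
    R: int,
    mapping: dict[Cell, str],
    name: str = "custom",
    category_switch: str = "distinct",
) -> ModelSpec:
    """Explicit cell -> parameter-key map over the allowed within-category cells.

    Cells absent from the mapping become structural zeros. For R=2 the same
    map is applied to both categories (keys prefixed per category) and the
    standard switch parameters are appended.
    """
    ok = set(allowed_cells(k))
    for c in mapping:
        if c not in ok:
            raise ValueError(f"cell {c} is not an allowed transition for k={k}")
    m = k * R
    pi = -np.ones((m, m), dtype=int)
    key_to_idx: dict[str, int] = {}
    names: list[str] = []

    def idx_for(key: str) -> int:
        if key not in key_to_idx:
            key_to_idx[key] = len(names)
            names.append(key)
        return key_to_idx[key]

    for cat in range(R):
        off = cat * k
        for (a, b), key in mapping.items():
            pi[off + a, off + b] = idx_for(f"R{cat + 1}.{key}" if R > 1 else key)
    if R == 2:
        keys = ("switch.R1R2", "switch.R2R1") if category_switch == "distinct" else ("switch", "switch")
        for s in range(k):
            pi[s, k + s] = idx_for(keys[0])
            pi[k + s, s] = idx_for(keys[1])
    return ModelSpec(name=name, k=k, R=R, param_index=pi, param_names=tuple(names))


def build_q(spec: ModelSpec, params) -> np.ndarray:
    """Generator matrix from a parameter vector (events per time unit, > 0)."""
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.k_free,):
        raise ValueError(f"expected {spec.k_free} parameters, got {params.shape}")
    if not np.all(np.isfinite(params)) or np.any(params <= 0):
        raise ValueError("rates must be strictly positive and finite")
    Q = np.zeros((spec.m, spec.m))
    mask = spec.param_index >= 0
    Q[mask] = params[spec.param_index[mask]]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt), clamped into [0, 1]."""
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"duration must be finite and >= 0, got {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    P = scipy.linalg.expm(np.asarray(Q, dtype=float) * t)
    return np.clip(P, 0.0, 1.0)


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Qt) for a whole vector of durations at once.

    Uses one eigendecomposition and broadcasts over branches; falls back to
    per-branch ``expm`` when Q is defective or ill-conditioned. Returns an
    array of shape (len(ts), m, m).
    """
    Q = np.asarray(Q, dtype=float)
    ts = np.asarray(ts, dtype=float)
    m = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            E = np.exp(np.multiply.outer(ts, w))  # (B, m)
            P = np.einsum("ij,bj,jk->bik", V, E, Vinv)
            P = np.ascontiguousarray(P.real)
            rowerr = np.abs(P.sum(axis=2) - 1.0).max() if P.size else 0.0
            if rowerr < 1e-10 and P.min() > -1e-10:
                return np.clip(P, 0.0, 1.0)
    except np.linalg.LinAlgError:
        pass
    out = np.empty((len(ts), m, m))
    for i, t in enumerate(ts):
        out[i] = transition_probabilities(Q, float(t))
    return out
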