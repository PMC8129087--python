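"""Maximum-likelihood fitting with multi-start optimization, AICc and weights."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .likelihood import RootPolicy, prune_loglik, tip_partials
from .models import ModelSpec, build_q
from .phylo import Phylogeny, write_newick

__all__ = ["FitResult", "aicc", "fit_model", "compare_models", "parsimony_changes"]

RATE_BOUNDS = (1e-9, 1e2)  # events per time unit
_BIG = 1e12  # stand-in objective for -inf log-likelihoods


def aicc(lnL: float, k_free: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); n = number of terminal taxa."""
    if n <= k_free + 1:
        raise ValueError(f"AICc undefined: need n > k+1 (n={n}, k={k_free})")
    return -2.0 * lnL + 2.0 * k_free + (2.0 * k_free * (k_free + 1)) / (n - k_free - 1)


def parsimony_changes(tree: Phylogeny, states: dict[str, int | None], k: int) -> int:
    """Fitch parsimony count of state changes; missing tips are unconstrained.

    Used only to seed the optimizer with a rate of plausible magnitude.
    """
    full = frozenset(range(k))
    sets: dict[int, frozenset[int]] = {}
    changes = 0
    for nd in tree.postorder():
        if nd.is_tip:
            s = states.get(nd.label)
            sets[nd.id] = full if s is None else frozenset([s])
            continue
        acc: frozenset[int] | None = None
        for c in nd.children:
            cs = sets[c]
            if acc is None:
                acc = cs
            else:
                inter = acc & cs
                if inter:
                    acc = inter
                else:
                    acc = acc | cs
                    changes += 1
        sets[nd.id] = acc if acc else full
    return changes


@dataclass
class FitResult:
    """One model's MLE and score; every field needed to re-derive AICc."""

    spec: ModelSpec
    params: np.ndarray
    lnL: float
    k_free: int
    n: int
    aicc: float
    nstarts: int
    start_lnls: list[float]
    converged: bool
    seed: int
    fingerprint: str = ""
    clamped: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = self.spec.name


def _fingerprint(tree: Phylogeny, states: dict[str, int | None]) -> str:
    h = hashlib.sha256()
    h.update(write_newick(tree).encode())
    for sp in sorted(states):
        h.update(f"{sp}={states[sp]};".encode())
    return h.hexdigest()[:16]


def fit_model(
    tree: Phylogeny,
    states: dict[str, int | None],
    spec: ModelSpec,
    root: RootPolicy,
    clamps=(),
    nstarts: int = 10,
    seed: int = 1,
    maxiter: int = 500,
    name: str | None = None,
) -> FitResult:
    """Maximize the pruning log-likelihood over log-transformed rates.

    The first start uses a parsimony-informed equal-rates heuristic; the
    remaining starts draw rates log-uniformly. Deterministic given ``seed``.
    All per-start optima are retained so multimodality stays visible.
    """
    if nstarts < 1:
        raise ValueError("nstarts must be >= 1")
    tips = tip_partials(tree, states, spec.k, spec.R)
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def negloglik(x: np.ndarray) -> float:
        Q = build_q(spec, np.exp(x))
        ll = prune_loglik(tree, tips, Q, root, clamps, spec=spec)
        return _BIG if not np.isfinite(ll) else -ll

    total_len = tree.total_branch_length()
    nch = max(parsimony_changes(tree, states, spec.k), 1)
    r0 = float(np.clip(nch / total_len, *RATE_BOUNDS))
    rng = np.random.default_rng(seed)
    starts = [np.full(spec.k_free, np.log(r0))]
    for _ in range(nstarts - 1):
        starts.append(rng.uniform(np.log(1e-4), np.log(10.0), size=spec.k_free))

    best: scipy.optimize.OptimizeResult | None = None
    start_lnls: list[float] = []
    failures: list[str] = []
    for x0 in starts:
        try:
            res = scipy.optimize.minimize(
                negloglik,
                x0,
                method="L-BFGS-B",
                bounds=[(lo, hi)] * spec.k_free,
                options={"maxiter": maxiter, "ftol": 1e-10},
            )
        except Exception as exc:  # pragma: no cover - optimizer blow-up
            failures.append(str(exc))
            continue
        start_lnls.append(float(-res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {nstarts} optimizer starts failed: {failures}")

    lnL = float(-best.fun)
    try:
        score = aicc(lnL, spec.k_free, tree.n_tips)
    except ValueError:
        score = float("nan")  # n too small for the correction; lnL still valid
    ordered = sorted(start_lnls, reverse=True)
    converged = len(ordered) < 2 or (ordered[0] - ordered[1]) < 1e-4
    return FitResult(
        spec=spec,
        params=np.exp(best.x),
        lnL=lnL,
        k_free=spec.k_free,
        n=tree.n_tips,
        aicc=score,
        nstarts=nstarts,
        start_lnls=start_lnls,
        converged=bool(converged),
        seed=seed,
        fingerprint=_fingerprint(tree, states),
        clamped=bool(clamps),
        name=name or spec.name,
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """AICc comparison table: model, neg_lnL, k, AICc, dAICc, weight.

    All fits must be on the same tree/tip data (checked via fingerprint).
    Sorted ascending by AICc; weights are exp(-dAICc/2) normalized.
    """
    if not fits:
        raise ValueError("no fits to compare")
    fps = {f.fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits come from different datasets (fingerprint mismatch)")
    rows = []
    for f in fits:
        rows.append({"model": f.name, "neg_lnL": -f.lnL, "k": f.k_free, "AICc": f.aicc})
    df = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    rel = np.exp(-0.5 * df["dAICc"].to_numpy())
    df["weight"] = rel / rel.sum()
    return df
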