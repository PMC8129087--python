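# mkevo

Discrete-trait Markov (Mk) models on time-calibrated phylogenies:
constrained and hidden-rate generator matrices, maximum-likelihood fitting
with multi-start optimization, AICc model comparison with Akaike weights,
node-clamped hypothesis tests, marginal ancestral-state reconstruction with
transition counting, and a synthetic-data generator with recorded ground
truth.

## What it does

- **`mkevo.phylo`** — Newick trees (polytomies, quoted labels, exact
  round-trip), CSV trait tables with missing data, mrca/pruning/traversals,
  tree–trait alignment.
- **`mkevo.models`** — declarative rate-matrix families: ER, ARD, IND
  (independent joint evolution), ARD_loss (tied loss rates), two-category
  hidden-rate variants (ER/ER, ARD/ARD, ER/ARD), and arbitrary custom
  cell→parameter maps; transition probabilities via the matrix exponential.
- **`mkevo.likelihood`** — Felsenstein pruning with per-node rescaling,
  flat or fixed-state root policies, internal-node state clamps, and a
  brute-force enumeration oracle for small trees.
- **`mkevo.fit`** — multi-start L-BFGS-B in log-rate space, AICc, and
  model-comparison tables (model, −lnL, k, AICc, ΔAICc, weight).
- **`mkevo.ancestral`** — exact marginal posteriors at every node (two-pass
  up–down algorithm, hidden categories summed out) and MAP transition
  tallies reported as [min, max] ranges with an ambiguity threshold.
- **`mkevo.simulate`** — Yule chronograms, Gillespie trait histories with
  every event recorded, and a 292-tip end-to-end fixture.

## Command line

```sh
# simulate a chronogram + trait history with recorded truth
mkevo simulate --tips 100 --height 200 --model ARD --rates 0.01,0.02 --seed 1 --out run/sim

# fit single-trait models (IO = ARD with the named clade clamped)
mkevo fit --tree run/sim/tree.nwk --traits run/sim/traits.csv \
    --models ER,ARD,ER/ER,ER/ARD --root-state 0 --nstarts 100 --seed 1 --out run/fit

# marginal ancestral states + transition tally under one model
mkevo ancestral --tree run/sim/tree.nwk --traits run/sim/traits.csv \
    --model ARD --root-state 0 --out run/anc

# joint evolution of two binary traits (4-state coding, order (t1,t2))
mkevo joint --tree tree.nwk --traits traits.csv --models ER,IND,ARD,ARD_loss \
    --clade tipA,tipB --out run/joint

# materialize the 292-tip test fixture; prune a tree to a clade
mkevo fixtures --seed 1 --out run/fixture
mkevo prune --tree tree.nwk --tips tipA,tipB,tipC --out sub.nwk
```

Every run writes a `manifest.json` (input hashes, seed, version) sufficient
to reproduce its outputs bit-identically.

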