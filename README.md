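# rhpcbn

Constraint-based Bayesian network structure learning built around the
**HPC** (Hybrid Parents and Children) local learner and its whole-network
recursion **RHPC**, with bootstrap consensus-network aggregation and a
structure-recovery benchmark harness.

## What's inside

| module | contents |
| --- | --- |
| `rhpcbn.graph_core` | `DirectedGraph`, `PartialDAG`, d-separation (ancestral moralization), Markov boundaries, essential graphs (v-structures + Meek rules), random DAG generation |
| `rhpcbn.ci_tests` | conditional-independence tests sharing one signature: G² / Pearson χ² (discrete, with an insufficient-data guard), Fisher z (continuous), and a d-separation oracle for validation; CSV/YAML dataset IO |
| `rhpcbn.weak_learner` | Inter-IAMB Markov-boundary learner and the Inter-IAPC parents-and-children learner |
| `rhpcbn.hpc` | DE-PCS / DE-SPS data-efficient supersets (all conditioning sets of size ≤ 2), sepset caching, and the HPC decentralized ensemble |
| `rhpcbn.rhpc` | skeleton assembly (OR/AND rule), v-structure orientation from cached separating sets, Meek propagation |
| `rhpcbn.consensus` | bootstrap resampling, directional edge confidences, threshold consensus PDAGs |
| `rhpcbn.benchmark` | `BayesNet` with BIF read/write, ancestral sampling, the (1−precision)² + (1−recall)² recovery distance, the hub-recovery experiment runner, and deterministic fixtures (incl. a 35-node / 52-edge network with a degree-13 hub) |

## CLI

```sh
# essential-graph estimate from one dataset (CSV with header; integer
# columns are treated as discrete, otherwise continuous; --schema overrides)
rhpcbn learn --data data.csv --alpha 0.05 --test g2 --out net.json

# bootstrap consensus PDAG with directional edge confidences
rhpcbn bootstrap --data data.csv --replicates 200 --threshold 0.25 \
    --seed 1 --out consensus.dot --confidences confidences.csv

# hub-recovery benchmark on a gold-standard network (BIF) or the built-in
# fixture; AUTO_MAX_DEGREE targets the highest-degree node
rhpcbn benchmark --fixture insulin_like --target AUTO_MAX_DEGREE \
    --sizes 200,500,1000,2000 --reps 20 --seed 1 --out results.csv
```

`.dot` outputs render undirected edges with `dir=none` and carry consensus
confidences as `penwidth`/labels; `.json` outputs hold
`{nodes, directed, undirected}`.

## Notes

- All learners are deterministic given the data; every stochastic component
  (sampling, bootstrap, fixtures) takes an explicit seed.
- Discrete tests refuse to reject independence when fewer than 10 rows per
  degree of freedom are available (configurable), which is what makes the
  superset routines usable on small samples.
- The bootstrap consensus inherits each original sample's idiosyncratic
  correlations; spurious-edge confidences therefore concentrate just below
  the default 25% inclusion threshold.
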