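# evidenceflow

Evidence flow, random-walk evidence streams, and proportion contributions
for frequentist network meta-analysis (NMA).

## The problem

An NMA pools randomized trials comparing several treatments into one
weighted graph: nodes are treatments, an edge ab carries the pooled direct
estimate θ̂ᵈⁱʳ_ab and its inverse-variance weight w_ab.  When assessing
risk of bias it is not enough to know the network estimate θ̂ⁿᵉᵗ_ab — one
needs to know *how much each direct comparison contributed to it*, because
a biased trial on edge cd taints every network estimate that draws on cd.

The aggregate model answers this with the hat matrix

    H = B (BᵀWB)⁺ BᵀW,        θ̂ⁿᵉᵗ = H θ̂ᵈⁱʳ,

where B is the signed edge-incidence matrix, W = diag(w_ab), and
L = BᵀWB is the graph Laplacian.  Row ab of H, split by sign, is a
directed acyclic **evidence flow network**: a unit of evidence leaves a,
arrives at b, and is conserved at every intermediate node.  Multi-arm
trials are handled by converting each trial's pairwise variance matrix
into an equivalent complete subgraph of two-arm comparisons (the
variance ↔ resistance correspondence), so within-trial correlations are
respected.

This package implements the random-walk formulation of that flow:

* **Walk on the aggregate network** — a walker hops with probabilities
  T_cd = w_cd / Σ_x w_cx; the expected net number of times a walker going
  from a to b crosses edge cd equals the electrical current through cd and
  therefore the hat-matrix element H_cd(ab).  Both the exact
  (Laplacian-pseudoinverse) route and a vectorized Monte Carlo validator
  are provided.
* **Walk on the evidence flow network** — normalizing each node's outgoing
  flows gives a transition matrix U(ab); every source-to-sink path πᵢ is an
  *evidence stream* with flow φᵢ = ∏ U along the path.  The **proportion
  contribution** of direct comparison cd to the ab estimate is
  p_cd(ab) = Σ_{i: cd∈πᵢ} φᵢ/|πᵢ|, an analytical, order-free quantity.
* **Legacy iterative algorithm** (Shortest / Random / Average variants) —
  the earlier min-flow path-subtraction scheme, kept for comparison; its
  output depends on selection order and it can miss evidence paths.

## Worked example

The four-treatment topical-antibiotics network (1 = no treatment,
2 = quinolone antibiotic, 3 = antiseptic, 4 = non-quinolone antibiotic)
ships as a fixture with the flow network for the comparison 1-2:

```python
import evidenceflow as ef

fn = ef.fixture("macfadyen_flow")          # flows: 1→2: .635, 1→3: .365, 3→2: .251, 3→4: .114, 4→2: .114
print(ef.check_conservation(fn, tol=1e-3).ok)

model = ef.flow_transition_matrix(fn)
paths = ef.enumerate_paths(fn)
for s in ef.stream_flows(model, paths):
    print(s.name, round(s.flow, 3))
```

prints

```
True
1→2 0.635
1→3→2 0.251
1→3→4→2 0.114
```

i.e. 63.5% of the evidence for the 1-2 effect flows through the direct
comparison, 25.1% through the antiseptic detour 1→3→2, and 11.4% through
the three-edge path 1→3→4→2.  The resulting proportion contributions
(`ef.proportion_contributions(...)`) are 0.635 for edge 1-2, 0.1635 for
1-3, 0.1255 for 3-2, and 0.038 for each of 3-4 and 4-2.

The estimator surface composes with scikit-learn conventions:

```python
from evidenceflow import EvidenceFlowNMA, SyntheticSpec, generate_synthetic

trials, truth = generate_synthetic(SyntheticSpec(seed=42))
est = EvidenceFlowNMA(tau2=0.0).fit(trials)     # or fit a contrast DataFrame
est.hat_matrix_                                  # K×K labelled DataFrame
est.contributions(1, 2)                          # per-edge proportions, sums to 1
est.transform(est.direct_estimates_.values)      # H · θ̂ᵈⁱʳ
```

A CLI mirrors the library for shell use:

```
evidenceflow synth --treatments 6 --trials 12 --seed 4 --out data.csv
evidenceflow hat --input data.csv --tau2 0 --out hat.csv
evidenceflow contributions --input data.csv --comparison 1,2
evidenceflow simulate --input data.csv --comparison 1,2 --walkers 100000 --seed 42
```

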