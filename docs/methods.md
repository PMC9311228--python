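# Methods

## Model

The package implements the two-step ("aggregate") frequentist NMA model on
the graph-theoretical formulation.  Contrast-level data consist of rows
(study, treatment a, treatment b, Y, σ) with Y the observed effect of b
relative to a on the analysis scale.  Analysis proceeds in three layers:

1. **Per-trial adjustment.**  A two-arm trial gets weight
   w = 1/(σ² + τ²).  An n-arm trial reports all q = n(n−1)/2 pairwise
   contrasts; its q total variances (heterogeneity τ² added *before*
   adjustment) form a matrix V of resistance distances.  With the
   centering matrix C = I − J/n, the trial Laplacian is
   L_i = pinv(−½ C V C) and the adjusted weights are its negated
   off-diagonal entries.  This is the variance ↔ resistance
   correspondence: the equivalent complete two-arm subgraph reproduces the
   trial's joint precision exactly (tested against a one-step GLS oracle
   with the full within-trial covariance).  For the symmetric three-arm
   case (all variances v) the adjusted weight is 2/(3v) — adjusted
   variance 1.5 v, the familiar √1.5 standard-error inflation.
2. **Pooling.**  Edge weights w_ab sum the adjusted per-trial weights; the
   direct estimate is the weight-weighted mean of the (canonically
   oriented) observed effects.  The canonical orientation puts the
   treatment with the smaller label first (numeric order for integer-like
   labels, lexicographic otherwise); this fixes the sign conventions of
   B and H and makes all outputs reproducible.  The choice is
   substance-free: reversing an orientation flips the corresponding H row
   and column signs consistently and leaves the flow networks unchanged
   (tested).
3. **Network solution.**  B (K×N signed incidence), W = diag(w_ab),
   L = BᵀWB, and H = B L⁺ BᵀW.  H is idempotent and projects direct
   estimates onto the consistent subspace (potential differences on the
   graph).

## Random-walk formulations

*Aggregate walk.*  T_cd = w_cd/Σ_x w_cx with zero diagonal; for a
comparison ab, row b is replaced by the unit vector (absorption).  The
expected net number of crossings of edge cd by a walker released at a
equals the current through cd when a unit current is driven from a to b:
computed exactly from potentials v = L⁺(e_a − e_b) and currents
I_cd = w_cd(v_c − v_d), which equal the ab hat-matrix row elementwise.
The Monte Carlo simulator advances all walkers in lock-step numpy batches,
accumulating per-walker signed crossing counts so that standard errors of
the mean are available; it exists to validate the analytic identity and
for pedagogy, never as the computational route.

*Flow-network walk.*  Row ab of H, split by sign with tolerance 1e-12
(entries below it are structural zeros, not edges — the printed form of
the model does not define a sign for exact zeros, so they are treated as
"no edge"), gives a DAG carrying a unit flow.  Normalizing outgoing flows
yields U(ab); the sink row is a unit vector, and nodes isolated in this
comparison's flow network are given a unit diagonal (a walker starting
there never moves).  Paths are enumerated depth-first with successors
visited in label order — a deterministic, reproducible order — and each
path's flow is the product of U entries along it.  Flows are non-negative
and sum to one; contributions p_cd(ab) = Σ φᵢ/|πᵢ| over paths through cd
sum to one per comparison.  Contribution rows exist only for observed
comparisons (edges), since hat-matrix rows are defined only there; defining
rows for indirect-only pairs would require an augmented hat matrix and is
deliberately out of scope.

*Legacy iterative algorithm.*  Repeatedly select a remaining
source-to-sink path, assign it the minimum residual flow on its edges,
subtract, drop exhausted edges; stop when no path remains (each iteration
exhausts at least one edge, so at most K iterations).  Variants: Shortest
(shortest-first, ties broken by lexicographic node sequence — the
published descriptions leave the tie-break open, so exact replication of
third-party runs is not guaranteed), Random (uniform over all currently
feasible paths, re-enumerated each iteration), Average (mean over n_iter
seeded Random runs, default 1000; convergence to the walk result is not
claimed and does not generally hold, which is precisely the motivation for
the analytical walk).

## Numerical choices

- Pseudoinverses of PSD matrices use an eigendecomposition with a relative
  eigenvalue cutoff of 1e-12, keeping explicit control of the rank-(N−1)
  null space of a connected Laplacian.
- Adjusted weights in (−1e-10, 0) are clipped to zero (round-off);
  anything more negative raises "inadmissible variance pattern" — such
  patterns imply a negative arm variance and cannot come from real
  arm-level data.
- Pooled edges below 1e-12 of the largest pooled weight are dropped as
  zero-weight (infinite-variance) comparisons.
- Flow networks are verified acyclic by topological sort rather than
  assumed; a cycle would signal numerical corruption upstream.
- Path enumeration carries a configurable cap (default 10⁶ paths) and
  raises an informative error instead of exhausting memory on dense
  networks where the path count grows exponentially.
- Walker simulation: max_steps defaults to 10⁶ as a safety valve
  (absorption is certain on a connected network); all randomness flows
  through one seeded `numpy` generator.

## Synthetic data generator

`generate_synthetic` emulates the contrast-level data model: treatment
"potentials" drawn once per data set, true effects as potential
differences (consistent by construction), and Gaussian noise generated at
**arm level** — one latent draw per arm — so that the q contrasts of a
multi-arm trial have exactly the covariance structure the adjustment
assumes (variances add across the two arms; contrasts sharing an arm
covary).  Heterogeneity is emulated as an extra τ²/2 variance per arm.
Defaults describe a realistic published-network shape: 11 treatments, 26
trials, about a third multi-arm with up to four arms, contrast standard
errors uniform on (0.2, 0.8) on a log odds-ratio scale, τ² = 0
(fixed-effect).  Connectivity is enforced by regeneration (bounded
retries).

What the generator does *not* emulate: arm-level event counts (so no
rare-event or zero-cell behaviour), between-trial heterogeneity beyond a
common τ², inconsistency (true effects are exactly consistent), and
non-random structural patterns such as comparator preferences.  Passing
tests therefore demonstrate correctness of the linear-algebraic and
graph machinery under the stated model, not robustness to violations of
it.

## Test problem sizes

Property checks run on networks of 5–11 treatments with 8–26 trials; the
equivalence suite covers 50 random networks of up to 10 nodes; the Monte
Carlo validation uses 10⁵ walkers on the five-node worked example; the
Average legacy variant uses small iteration counts (5–30) in tests, with
1000 as the package default.  These sizes exercise every code path —
multi-arm adjustment, isolated flow-network nodes, exponential-path
guards — while keeping the default suite fast.

## Known limitations

- τ² is an input; no heterogeneity estimator is included.
- Contributions for comparisons without direct evidence are not defined.
- Arm-level (one-step) models, Bayesian estimation, meta-regression, and
  ranking metrics are out of scope.
- The Shortest/Random variants reproduce the *behaviour class* of the
  published algorithm; exact third-party outputs depend on unspecified
  tie-breaking and sampling details.
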