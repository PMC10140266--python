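# Methods

## The estimation problem

A relative binding free energy network consists of a congeneric ligand
series (nodes), alchemical transformations between structurally similar
pairs (edges), and, per edge, two thermodynamic legs: the transformation
carried out with the ligand bound in the receptor (complex) and free in
water. The edge observable is ΔΔG = ΔG_complex − ΔG_water. In the
non-equilibrium switching (NES) protocol each leg is sampled by an
equilibrium simulation at both physical end states followed by many short
driven transitions in which the coupling parameter λ is swept continuously
from one end state to the other; the work of each transition is obtained by
thermodynamic integration of ∂H/∂λ along the sweep.

This package implements everything downstream of (and around) the engines:
pose filtering, map construction, work processing, estimation, graph
reconstruction and benchmarking. The engines themselves (docking, MD,
hybrid-topology setup) are replaced by mock backends that write the same
file formats.

## Free energy estimator

Forward (A→B) and reverse (B→A) work samples obey the Crooks fluctuation
theorem, P_f(W)/P_r(−W) = exp(β(W − ΔG)) with β = 1/k_BT. The
maximum-likelihood estimate given n_f forward and n_r reverse samples is
the root of the Bennett self-consistency condition

    Σ_i [1 + (n_f/n_r) exp(β(W_f,i − ΔG))]⁻¹
  − Σ_j [1 + (n_r/n_f) exp(β(ΔG + W_r,j))]⁻¹ = 0,

where reverse works W_r are recorded as integrated along the B→A sweep
(so W_r ≈ −W_f for a reversible process). The left side is monotone in ΔG,
so the root is unique; it is bracketed by
[min(W_f ∪ −W_r) − 50 k_BT, max(W_f ∪ −W_r) + 50 k_BT] and solved with
Brent's method (a bracketed method, equally safe as bisection on a monotone
function and faster) to 10⁻¹² kcal/mol. Fermi factors are evaluated with
the logistic function, so both tails are overflow-free.

When the forward and negated-reverse work distributions are disjoint by
many k_BT, every Fermi weight underflows and the objective is numerically
zero across the gap: the root is undetermined. The estimator detects this
(total Fermi mass at the root below 10⁻¹⁰) and refuses with an
insufficient-overlap error rather than returning an arbitrary point of the
plateau.

The Jarzynski exponential average, ΔG = −k_BT ln⟨e^{−βW}⟩ computed with
log-sum-exp stabilisation, is provided for unidirectional data and as an
independent cross-check; it is never used in the pipeline proper.

### Units and constants

All internal energies are kcal/mol with k_B = 0.0019872041 kcal/(mol K) and
a default temperature of 298 K (the simulation protocol's thermostat
setting). Work and dH/dλ files are read in kJ/mol and converted (÷4.184) at
the boundary.

### Uncertainties

Per work set, the bootstrap SE is the SD of the estimator over resamples of
W_f and W_r drawn independently with replacement (default 100 resamples,
seeded). Independent replicas of the full protocol (default 3) are combined
as

    value = mean(ΔG_i),   se² = s²/R + (Σ_i se_boot,i²)/R²,

i.e. the standard error of the replica mean plus the propagated mean
bootstrap variance — both sources the error model names. The exact
combination rule used by existing NES analysis codes is not published; this
one is declared rather than claimed identical. For a single replica the
bootstrap SE passes through. Leg errors enter ΔΔG in quadrature.

## Frame schedule and work integration

From a production trajectory of length T with the first T₀ discarded as
extra equilibration, n frames are extracted at times T₀ + k(T−T₀)/n,
k = 1…n: the discard boundary is excluded and the final time is exactly T.
The production protocol (T = 6 ns, T₀ = 2 ns, n = 80) yields 50 ps spacing.
Work is the trapezoidal integral of ∂H/∂λ over λ in the traversal
direction; the trapezoid rule is exact for the constant and linear traces
used as oracles. Integration is performed in λ (not time), which is the
natural variable when the λ(t) schedule is linear and remains well defined
when it is not.

## Pose filtering

MCS search (RDKit FMCS) is restricted to heavy atoms with element-exact
matching; ring atoms match only ring atoms and ring bonds only ring bonds,
with a 10 s timeout and a minimum of 3 heavy atoms. The strictness is
deliberate: chemically loose mappings (aryl onto alkyl) make the pose RMSD
meaningless. All automorphic placements of the MCS on the reference are
enumerated and each pose scores its minimum RMSD over them, so an aromatic
ring flip cannot inflate the RMSD of an otherwise correct pose. RMSD is
computed without superposition — docked and reference poses share the
receptor frame, and superposing would mask exactly the binding-mode
inversions the filter exists to catch. Ties break to the lowest pose index,
preserving the engine's own ranking.

## Perturbation map construction

Edges are scored by MCS similarity, s = |MCS| / max(heavy atoms), in
[0, 1]. Kruskal's algorithm on distance 1 − s (ties by lexicographic edge
id, so construction is deterministic) yields a spanning tree; remaining
pairs are then added in decreasing similarity while either endpoint is
below the target degree (default 2, so every ligand lies on a cycle). This
is a transparent, testable alternative to external map generators, and it
guarantees the cycles the closure analysis requires. Maps are stored as
directed edges a→b with a < b lexicographically — a storage convention
only.

## Cycle closure and absolute ΔG

Node free energies g minimise Σ_e w_e (g_b − g_a − ΔΔG_e)² with
w_e = 1/max(se_e, 0.1 kcal/mol)²; the SE floor prevents a zero-error edge
from acquiring infinite weight. The minimiser solves the weighted graph
Laplacian by pseudo-inverse; the gauge is fixed to mean(g) = 0 and node SEs
are taken from the diagonal of the pseudo-inverse. The corrected edge
values g_b − g_a sum to zero around every cycle by construction — the
least-squares projection is the cycle-closure correction, realised in one
step rather than by per-cycle redistribution (same minimiser, unique
solution). For comparison with experiment all g are shifted by one constant
so that the calculated mean matches the experimental mean over measured
ligands; pairwise differences, the actual predictions, are untouched.

## Benchmark metrics

AUE = mean |calc − exp|, RMSE = √mean (calc − exp)², Pearson ρ, and Kendall
τ in its tie-corrected τ_b form (ties are expected on affinity data quoted
to 0.1 kcal/mol). Confidence intervals are percentile 2.5/97.5 bootstrap
over resampled (calc, exp) pairs. The experimental null band answers "what
would these metrics look like if the calculation were exactly as uncertain
as the experiment?": each draw perturbs the experimental vector twice with
independent Gaussian noise of SD max(σ_exp, 0.43 kcal/mol) — the floor is
the best-practice lower bound on affinity uncertainty — and scores one
replica against the other. Two independent draws, rather than one draw
against the original, because the ceiling being modelled involves noise on
both axes; the resulting RMSE band centres on σ√2.

## Synthetic data

For equal variances, the unique Gaussian pair satisfying the Crooks
relation for a target ΔG is

    W_f ~ N(ΔG + σ²/2k_BT, σ²),   W_r ~ N(−ΔG + σ²/2k_BT, σ²),

so σ (the per-direction dissipation scale) is the single noise knob of the
mock NES backend. Defaults mirror the production protocol: 80 transitions
per direction, 3 replicas per leg, σ = 1 kcal/mol (a typical well-behaved
edge). The water leg is generated with leg ΔG = 0 and the complex leg with
leg ΔG = ΔΔG — a convenience; the estimator sees only work values.

Synthetic map studies place true node ΔG uniformly over a 4.3 kcal/mol span
(the scale of the benchmark congeneric series) on an n-cycle topology with
chords added to degree 3. Degree 3 rather than the map builder's default 2:
on a pure 20-cycle the mean node variance under mean-zero gauge is
σ²(n²−1)/12n ≈ (1.3 σ)², i.e. a ring cannot average edge noise down, while
one extra edge per node brings the node RMSE well below the per-edge SD —
the redundancy real map generators provide. Experimental tables are truth
plus N(0, 0.43 kcal/mol) noise by default.

Pose fixtures are rigid random translations of the reference with exact,
per-pose displacement norms, so mapped RMSD equals the displacement and the
correct selection is known analytically. An optional rotation (degrees per
Å of displacement) can roughen the sets; it is off by default because it
breaks the exact-RMSD identity the oracle tests rely on.

What the generators do *not* emulate: non-Gaussian work distributions
(bimodality from conformational traps, slow-degree-of-freedom tails),
pose-dependent work statistics, charge-changing edges, and correlated
errors between edges sharing a ligand. Passing tests therefore demonstrate
the correctness of the estimators and plumbing under the stated noise
model, not the accuracy of NES on any particular protein system.

## Workflow runner

Configurations are JSON: an ordered step list plus global seed and
temperature. Steps exchange named artifacts; validation rejects unknown
step types, engine-stage names (docking/MD — pointed at the mock
equivalents) and bindings that reference artifacts no earlier step
produces. Every stochastic step receives a generator seeded by
global seed + step index; wall-clock times appear only in the log, so
`report.json` is byte-identical across reruns of the same configuration
and seed. A failing step halts the run, recording the step name and cause;
completed steps' artifacts are retained.

## Numerical choices and degenerate inputs

- BAR root: Brent on the stated bracket, xtol 10⁻¹² kcal/mol; overlap
  refusal at total Fermi mass < 10⁻¹⁰.
- Bootstrap: if more than 10% of resamples fail estimation the SE is
  refused rather than reported from the survivors.
- Zero-variance metric inputs: correlations are reported as undefined
  (NaN, flagged) while AUE/RMSE remain valid.
- Modal-charge ties in the charge filter are errors, not arbitrary picks —
  silently mixing charge states would invalidate every downstream edge.
- Degenerate bootstrap resamples (a single repeated pair) are redrawn.

## Problem sizes and calibration

The bundled experiments run at desk scale: recovery rates use 100 seeds at
1000 work samples (estimator) or 20 nodes (graph solve); the end-to-end
fixture uses 10 ligands × 3 replicas × 80 transitions over 20 seeds; CI
calibration uses 200 datasets of 30 ligand pairs with 1000 bootstrap
resamples.

Known limitation: the percentile bootstrap CI for RMSE undercovers
slightly at these sizes — measured ≈90% against a nominal 95% at 30 pairs —
as expected for the percentile method on a right-skewed statistic. The
interval construction is kept as the standard percentile form;
bias-corrected variants would narrow the gap at the cost of comparability.
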