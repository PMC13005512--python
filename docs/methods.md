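# Methods

`gaucherflux` builds and analyses paired healthy / Gaucher-disease (GD)
macrophage metabolic models with constraint-based techniques.  This note
describes the models, the algorithms, the synthetic data that stands in for
experimental inputs, and the numerical and design choices a user should
know before trusting (or extending) the results.

## Constraint-based model

A metabolic model is a stoichiometric matrix **S** (metabolites ×
reactions) with flux bounds `lb ≤ v ≤ ub` in umol/gDW/hr, gene–protein–
reaction (GPR) boolean rules, and subsystem labels.  Metabolite identifiers
carry their compartment as a `[x]` suffix (`c` cytosol, `m` mitochondrion,
`l` lysosome, `e` extracellular, `i` mitochondrial intermembrane protons).
Exchange reactions are written `1 met[e] →`, so secretion is positive flux
and uptake negative — the convention needed to compare predictions against
measured uptake/secretion rates directly.

Two consistency notions are checked (`gaucherflux.consistency`):

- *stoichiometric consistency* — existence of strictly positive metabolite
  weights orthogonal to every internal reaction column, solved as the LP
  feasibility problem `Sᵢₙₜᵀ w = 0, w ≥ 1`.  It certifies that no internal
  reaction creates mass from nothing.
- *flux consistency* — no reaction is blocked, i.e. every reaction can
  carry `|v| > tol` in some steady state, checked by per-reaction flux
  variability (two LPs per reaction).

Thermodynamic feasibility beyond these two checks is intentionally out of
scope; flux directionality is encoded in the bounds.

## Flux prediction

**FBA** maximises a linear objective over `{S v = 0, lb ≤ v ≤ ub}`
(scipy/HiGHS).

**Entropic FBA** adds a strictly convex flux-entropy term over split
forward/reverse fluxes:

max  c·(v_f − v_r) − g Σⱼ [v_fⱼ ln v_fⱼ − v_fⱼ + v_rⱼ ln v_rⱼ − v_rⱼ]

subject to `S(v_f − v_r) = 0`, `v_f ∈ [max(lb,0), max(ub,0)]`,
`v_r ∈ [max(−lb,0)… ]` — the split boxes encode the net bounds exactly.
The entropy weight `g` (default 1) trades objective value against flux
dispersion; strict convexity makes the solution unique, which is what lets
ensembles of entropic solutions be compared statistically.  The solver is
a damped semismooth Newton method on the metabolite potentials: the primal
is recovered in closed form `x(y) = clip(exp((c̃ − Aᵀy)/g), box)`, the dual
residual `A x(y)` is driven below 1e-9 (absolute) with a line search and
adaptive regularisation, and continuation in `g` (annealing from ≥ 1 down
to the requested weight) handles small entropy weights, where the solution
approaches an FBA optimum.  A trust-constr interior-point solve is the
fallback when Newton stalls.  Initialisation is deterministic (y = 0), so
repeated runs agree to solver tolerance.

Two properties of this objective matter for interpretation:

- at fluxes below e the per-reaction entropy term *rewards* activity, so
  moderate-flux side routes stay populated — the reason every usable
  reaction carries strictly positive activity `v_f + v_r`;
- the term is not positively homogeneous, so rescaling all bounds and
  demands by a common factor preserves ATP-fraction decompositions only
  approximately (measured ≈ 0.05 absolute drift at a 2× rescale on the toy
  network); the decomposition arithmetic itself is exactly scale-free, and
  exact invariance would hold in the linear-objective limit.

**MOMA** (minimisation of metabolic adjustment) projects a reference flux
vector onto the feasible polytope, `min ‖v − v_ref‖²`; it shares the dual
Newton machinery (quadratic instead of entropic potential) and is the
post-knockout predictor.

**Knockouts** evaluate each GPR with the knocked-out genes off and every
other gene on; reactions whose rule goes inactive get `lb = ub = 0`.

## Context-specific extraction

`extract_context_model` reduces a generic network to a flux-consistent
subnetwork that keeps every reachable core reaction (core = genes above
the FPKM > 10 activity threshold mapped through GPRs, plus explicitly
listed reactions).  The algorithm is a transparent greedy procedure:
blocked reactions are dropped first (core ones among them are reported as
unreachable, never silently lost); an L1-sparse LP finds a small support
carrying all core reactions at once; non-core reactions are then pruned in
descending connectivity order (ties lexicographic) whenever the core
remains supportable; finally, non-core reactions left blocked inside the
pruned subnetwork are removed.  All tie-breaking is deterministic.  On
random ≤ 12-reaction generics the result matches the exhaustive-search
minimum in ≈ 98–99% of instances (the greedy occasionally keeps one extra
reaction); `exhaustive_minimal_subnetwork` is the independent reference for
that comparison and is only tractable at toy size.

## Validation against measured exchange rates

Predicted exchange fluxes are compared with measured rates on three
levels: sign agreement (|flux| < 1e-9 counts as zero and agrees only with
zero), Spearman rank correlation (average ranks on ties), and a weighted
Euclidean distance with scale-free weights `wᵢ = 1/max(|measuredᵢ|, 1e-6)²`
so metabolites of different magnitudes are commensurable.  Measurements
flagged `excluded` (e.g. essential amino acids whose accumulation in spent
medium cannot constrain de-novo synthesis) are removed before all three
metrics.  Ensemble selection retains models passing accuracy ≥ 0.65 and
rank correlation ≥ 0.56 by default; the distance criterion is disabled by
default and all three are configurable.

## Disease-model construction

GD instances derive from a healthy reference by qualitative bound scaling,
which preserves the direction of transcriptional regulation without
pretending transcript abundance predicts catalytic capacity:

| rule | factor | robustness range |
|---|---|---|
| GBA1-catalysed reactions, upper bound | × 0.10 | — |
| down-regulated genes, upper bound (and positive lower bounds) | × 0.50 | 0.30–0.70 |
| up-regulated genes, lower bound | × 1.50 | 1.30–1.70 |

For an up-regulated reaction whose lower bound is not positive, "150% of
the reference" is undefined; the reference entropic flux stands in when it
is positive (the bound becomes 1.5× that flux, capped at the upper bound),
otherwise the bound is left unchanged and logged.  Reactions mapped by
both an up- and a down-regulated gene are left unchanged with a logged
conflict.  If the scaled model is infeasible, the up-scaled lower bounds
are proportionally relaxed toward their reference values by bisection
(≤ 50 steps).  With all three factors at 1 the construction is the
identity.

Differential expression is called by Welch's t-test on log2 values with
|log2 FC| > 1 and p < 0.05 defaults; the type-I rate of this test is
checked at ≈ 5% on null simulations.

Paired control/GD instances are filtered in flux space: entropic fluxes of
all instances are embedded by t-SNE (seeded, perplexity `min(30, n/3)`),
partitioned by 2-means, and a pair is retained when each member falls in
its condition's majority cluster.  Separation is declared at silhouette
> 0.25; without it, all pairs are kept with a warning — a deliberate
fail-open, since discarding pairs on an unsupported clustering would bias
the ensemble.

## Ensemble analytics

- **Simulation setup.**  The objective sums biomass_maintenance, ATPM,
  ATPS4mi and the first two ganglioside-synthesis reactions (weight 1
  each); ATPM and biomass_maintenance get lower bounds 44.8 and 3.45
  umol/gDW/hr (experimentally derived minimal-viability estimates); the
  lysosomal ganglioside uptake `EX_gangliosides[l]` is pinned to a level
  from {0.1, 1, 5, 10} umol/gDW/hr.
- **Condition ensembles.**  Instance variability is modelled by log-normal
  jitter (sd 0.05 on the log scale) of every finite nonzero exchange
  bound, one factor per reaction per instance, followed by an entropic
  solve.
- **Differential flux.**  Per reaction, total activity `a = v_f + v_r + ε`
  (ε = 1e-9); the statistic is the log2 ratio of ensemble mean activities
  with a two-sided Mann–Whitney U p-value across members; flags at
  |log2| > 1 and p < 0.05 (unadjusted by default; BH optional).  Activity
  rather than signed net flux keeps the ratio defined for reversible
  reactions, at the cost of conflating direction reversals with magnitude
  changes — net-flux means are therefore carried alongside wherever
  direction matters.  Reactions at zero activity in every member of both
  conditions are excluded from testing.
- **Enrichment.**  One-sided hypergeometric test per subsystem over the
  flagged set, BH-corrected.
- **GD-specific correlation modules.**  Spearman matrices per condition on
  net fluxes; a pair is GD-specific when |ρ_GD| ≥ 0.7 and |ρ_ctrl| ≤ 0.3;
  reactions in at least one such pair are clustered by average linkage on
  `1 − |ρ_GD|`, cut at 0.3; module gene lists come from the GPRs and are
  exported one gene per line for external regulatory-enrichment tools.
- **ATP decomposition.**  Tagged ATP-producing reactions (phosphoglycerate
  kinase and pyruvate kinase → glycolysis; succinyl-CoA ligase → citric-
  acid-cycle substrate-level phosphorylation; ATP synthase → oxidative
  phosphorylation) contribute `max(v, 0) ×` their ATP stoichiometry;
  fractions are normalised to total tagged production.  During the demand
  sweep ATPM is pinned (`lb = ub = level`): with ATPM also in the maximised
  objective, a free upper bound would drive demand to capacity at every
  level and the sweep would not vary anything.  Demand levels default to
  20–44.8 umol/gDW/hr, the range over which the disease models remain
  viable.
- **Robustness sweep.**  Disease construction and differential flux are
  re-run over the scaling ranges and all four uptake levels; the report
  gives, per reaction, the fraction of grid points agreeing in log-ratio
  sign with the default configuration.

## Reporter metabolites

Gene significance maps to z-scores `z = Φ⁻¹(1 − p)` (p clipped into
[1e-15, 1 − 1e-15]).  A metabolite's neighbours are the GPR genes of every
reaction touching it, excluding a configurable currency list (ATP/ADP/AMP,
NAD(H), NADP(H), CoA, quinones, water, phosphate, protons, O2, CO2) whose
ubiquity would otherwise swamp the statistic.  Raw score
`z_m = Σ z / √k`; the background correction subtracts the mean and divides
by the standard deviation of raw scores of `n_null` (default 10,000)
random size-k gene sets drawn without replacement from the scored-gene
universe, one shared null per k, with an upper-tail empirical p-value.
Only scored genes count toward k — this is what makes the corrected score
invariant to adding unscored genes, and it also means the "neighbourhood
larger than the universe" guard cannot fire in normal use.  The default
variant is two-tailed (z from a two-sided p); signed mean log2 fold
changes are reported alongside for direction.

A calibration worth knowing: after label permutation a formerly planted
hub behaves like a uniformly ranked metabolite, so it still lands in the
top decile about 10% of the time — "ranking destroyed" means chance-level
rank, not guaranteed absence from the top.

## Modifier-gene scoring

Knockouts are ranked by how far they move a source flux state toward a
target state.  The analysed reactions are partitioned from ensemble
differential flux: significance from the activity test, direction from the
net-flux means (for uptake exchanges activity and net direction disagree
in sign), giving R_F (net flux must rise), R_B (must fall) and R_S (must
stay).  For a knockout with movement `m_r = v_KO,r − v_src,r`:

wTS = Σ_{R_F} 1[m_r > δ_r] + Σ_{R_B} 1[−m_r > δ_r]
    − Σ_{R_S} min(|m_r|/s_r, 1),   s_r = max(|v_src,r|, 1)

evaluated at the MOMA prediction (worst case); bTS evaluates the same
functional at the knockout-feasible flux state maximising an LP surrogate
(capped linear credits, uncapped steady penalties); the robust score
rTS = min(bTS, wTS) when both share a sign, else 0.  The ensemble-mean
source flux is first projected onto the model's polytope by MOMA so that a
knockout touching nothing scores exactly zero.  The movement tolerance is
per-reaction: a credit fires only when the knockout achieves at least a
fraction (default 0.1) of the source-to-target gap of that reaction,
floored at 1e-6.  A single scalar floor would let indicator credits fire
on microscopic ripple movements that propagate through any tightly coupled
network, making every knockout score highly in both directions; the
gap-scaled tolerance is what gives the score its direction asymmetry.
Ranking scores every GPR-bearing gene (no pruning), descending by rTS,
ties lexicographic, infeasible knockouts last; the positivity threshold
for "identifying" a knockout is configurable and defaults to 0.

## The toy macrophage network

The synthetic generator emits a 96-reaction, 94-metabolite, 57-gene
network across c/m/l/e compartments: glycolysis (ATP at phosphoglycerate
kinase and pyruvate kinase), citric-acid cycle with succinyl-CoA ligase
(SUCLG1 and SUCLG2) substrate-level phosphorylation, lumped complex I and
a combined complex III+IV pumping protons for ATPS4mi, adenine-nucleotide
translocation into the cytosol, a malate/citrate shuttle feeding cytosolic
acetyl-CoA and a lumped cholesterol synthesis with ABCA1 export, the
sphingolipid branch (serine palmitoyltransferase → ceramide →
glucosylceramide, degraded by the GBA1 glucosylceramidase and acid
ceramidase in the lysosome), ganglioside phagocytosis
(`EX_gangliosides[l]`) with the stepwise lysosomal degradation chain and
the cytosolic synthesis route back to complex gangliosides, fatty-acid
beta-oxidation behind CPT1A, and the ATPM / biomass_maintenance
pseudo-reactions.  It is stoichiometrically consistent with no blocked
reactions by construction, and deterministic given its seed.

Deliberate design choices in the generator:

- the carnitine shuttle transfers the acyl moiety only, conserving the
  cytosolic and mitochondrial CoA pools (a naive acyl-CoA transporter
  would leak CoA across compartments and block beta-oxidation entirely);
- membrane turnover routes a constitutive glucosylceramide load
  (0.3 per biomass unit, ≈ 1 umol/gDW/hr at the viability bound) to the
  lysosome, so glucocerebrosidase has a substrate stream at every
  phagocytosis level — this is the macrophage's defining clearance burden
  and what makes the GBA1 knockdown bind robustly;
- undegraded glucosylceramide leaves through an exocytosis/redistribution
  exchange, the steady-state proxy for the lysosomal accumulation a
  steady-state model cannot represent directly;
- the fatty acid released by acid ceramidase exits as a generic efflux
  species rather than refilling the cytosolic palmitate pool; full salvage
  would let a ceramidase knockout masquerade as a therapeutic by merely
  shifting palmitate sourcing;
- the GBA1 and ceramidase steps are lumped without their water reactant:
  the forced degradation chain already drives the lysosomal water
  potential up with load, and a water-coupled salvage hydrolysis would be
  entropically suppressed at high phagocytosis rates for reasons that have
  nothing to do with the disease mechanism.

The planted disease signature (default differential-expression calls)
follows the expected GD macrophage biology: respiratory complexes,
pyruvate dehydrogenase and the ADP/ATP carrier down; glycolytic enzymes,
de-novo ceramide synthesis, cholesterol synthesis and late ganglioside
synthesis up (log2 FC ± 2).  The designated modifier gene is ASAH1 (acid
ceramidase): its knockout stalls lysosomal glucosylceramide clearance just
as the primary deficiency does, and it consistently tops the
healthy→disease transformation ranking.

Expression tables are log-normal FPKM-like values (baseline location 5.0
and spread 2.0 on the log2 scale, replicate noise sd 0.2, five replicates
per condition by default) with planted fold changes; exometabolome tables
are model-predicted exchange rates with multiplicative Gaussian noise.

### What the synthetic data does and does not show

The generator reproduces the *statistical structure* of the real inputs —
log-normal expression with planted direction, noisy signed exchange rates,
instance-to-instance bound variability — not their content.  Passing tests
demonstrate that the algorithms are correct and calibrated (type-I rates,
null reporter scores, solver accuracy, recovery of planted effects) and
that the disease-construction logic produces the qualitative phenotype its
inputs encode.  They say nothing about whether a genome-scale
reconstruction plus real transcriptomes would yield the same biology: the
toy network has no isozyme redundancy to speak of, class-level lipid
lumping, one representative reaction per pathway step, and exchange
capacities chosen for a viable, well-conditioned flux space rather than
measured medium composition.

## Numerical choices

- LP backend: scipy linprog/HiGHS; entropic/quadratic programs: the dual
  Newton scheme above (feasibility tolerance 1e-9 absolute, ≤ 10,000
  iterations across continuation stages), trust-constr fallback.
- Fluxes below 1e-9 are written as 0 in exports; full precision is kept
  internally.
- Spearman matrices symmetrise against floating noise before clustering;
  the 2-column case is special-cased around a scipy scalar-return quirk.
- t-SNE and 2-means are seeded; 2-means replaces visual cluster reading.
- All random draws flow from explicit integer seeds; nothing reads global
  RNG state.

## Problem sizes used in the shipped analyses

Toy network ≈ 96 reactions; condition ensembles of 10 instances (5 in the
robustness grid); extraction benchmarks on 100 random 10-reaction
generics against exhaustive search; statistical calibration on 2,000
genes / 2,000 reactions × 30-member ensembles; reporter nulls at
n_null = 10,000 over a 2,000-metabolite testbed.  These sizes make every
stage exactly checkable against brute-force or closed-form references
while the complete analysis remains a desk-scale computation.

## Known limitations

- The extraction greedy is not guaranteed minimum-cardinality (≈ 1–2% of
  small random instances keep one extra reaction).
- Mann–Whitney p-values across jittered ensemble instances treat
  instances as independent samples of a condition; the jitter model is a
  stand-in for real draft-model heterogeneity.
- The bound-scaling scheme encodes regulation direction only; magnitudes
  (10% / 50% / 150%) are qualitative knobs with robustness ranges, not
  measured capacities.
- Transformation scores rank structural reachability of a flux shift;
  they are not effect-size estimates and depend on the movement-tolerance
  convention described above.
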