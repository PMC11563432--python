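# Methods

## Model structure and units

An `EcModel` is an ordinary constraint-based metabolic model (stoichiometric
matrix **N**, flux bounds, a biomass reaction) augmented with enzymes
(molecular weight MW_i, g·mmol⁻¹), catalytic pairs (per enzyme–reaction
turnover number kcat_ij) and a proteome pool with capacity σ·f·P_total
(g·gDW⁻¹), where σ is the average in vivo saturation, f the mass fraction
of modelled enzymes and P_total the total protein content.  Fluxes are
mmol·gDW⁻¹·h⁻¹ and abundances mmol·gDW⁻¹, so kcat is h⁻¹ internally; all
user-facing reports convert to s⁻¹, the unit the field quotes.  GECKO SBML
files encode 1/kcat (in h) as the stoichiometric coefficient of a
`prot_<accession>` pseudo-metabolite; the importer inverts these
coefficients, recovers MW from the pool draw reactions, and records the
pool exchange bound as the capacity product (σ and f are not separately
recoverable from published files and are stored as 1).

Enzyme coupling uses per-pair usage variables: v_j = kcat_ij·u_ij for every
pair and Σ_j u_ij = E_i per enzyme.  A per-enzyme rate law v_j = kcat_ij·E_i
cannot hold simultaneously for a promiscuous enzyme with a single abundance;
the usage split is the standard GECKO resolution and reduces to the simple
form for single-reaction enzymes.  An inequality mode (Σ_j u_ij ≤ E_i) is
available for the variability analysis; on well-posed models the two modes
agree because idle enzyme mass is never beneficial, and the test suite
checks this agreement.

Multi-subunit complexes contribute one catalytic pair per subunit, each with
its own coupling row; isozymes remain split into parallel reaction arms.
Reactions without a catalytic pair (exchanges, spontaneous reactions) are
unconstrained by the pool.  Enzymatic reaction arms must be irreversible
(lb ≥ 0), enforced at validation.

## Wild-type reference (stage 1)

Three LPs on the same constraint set:

1. max v_bio → v_bio_opt.
2. max v_pro subject to v_bio ≥ (1−10⁻⁶)·v_bio_opt → v_pro_max.  The
   near-unity floor rather than an equality avoids knife-edge
   infeasibility when the optimal face is degenerate; the default is
   overridable (`bio_floor_frac`).
3. min Σ_i E_i subject to v_pro ≥ 0.98·v_pro_max and
   v_bio ≥ 0.98·v_bio_opt → E^wt, the usage split u^wt, and the minimal
   total usage Σe*.  The 0.98 retention factors are the standard slack
   that keeps the allocation LP off the degenerate optimal face; they are
   constants of the formulation, overridable in the API.

Robustness of E^wt is quantified by per-enzyme variability: min/max of E_i
subject to the same constraints plus Σ_i E_i = Σe* (the equality is widened
by the 10⁻⁹ feasibility tolerance so the stored optimum is re-attainable in
floating point).  The spread is reported as a stabilized log-ratio
log₁₀((e_max+ε)/(e_min+ε)) with ε = 10⁻⁹: bounded, monotone, and equal to
the plain ratio when both values ≫ ε.  Near-zero log-ratios justify using
E^wt as the anchor of the engineering stage.

## Engineering MILP (stage 2)

Variables: fluxes v, usages u_ij ≥ 0, abundances E_i, free auxiliaries
δe_ij (the linearized product δ_ij·u_ij) and binaries y_ij (1 = pair
unchanged).  Constraints per pair:

* engineered rate law v_j = kcat_ij·u_ij + δe_ij;
* −M·u_ij ≤ δe_ij ≤ M·u_ij (δe vanishes with usage);
* fold-change band kcat_ij(β₂⁻¹−1)·u_ij ≤ δe_ij ≤ kcat_ij(β₂−1)·u_ij;
* indicator rows ±δe_ij − β₁·kcat_ij·u_ij ≤ M_ij·(1−y_ij).

Plus the abundance band (1−α)E^wt ≤ E ≤ (1+α)E^wt, the pool constraint,
and the demands v_pro ≥ f_pro·v_pro_max, v_bio ≥ α_bio·v_bio_opt.  The
objective maximizes Σ y_ij, i.e. minimizes the number of significantly
changed turnover numbers.  Engineered values are recovered as
kcat* = kcat + δe/u for u above the 10⁻⁹ usage tolerance; zero-usage pairs
are reported unchanged with an explicit `indeterminate` flag (the big-M
row forces δe = 0 there, so no value can be recovered and none is
fabricated).

Defaults: α = 0.1, β₁ = 10⁻⁸, β₂ = 10, f_pro = 2, w = 10, β_e = 0.1,
M = 10⁶, MIP gap 0.  α_bio defaults to 0.85 and is mandatory-explicit in
the CLI: the growth retention of engineered designs is the one parameter
with a real modelling trade-off (nominally ≈ 1, in practice strategies
retain roughly 85–90% of optimal growth), so the user must choose it
consciously.

### Range-constrained mode with abundance modifications

When per-pair admissible ranges [kmin, kmax] (from turnover-prediction
catalogs) are supplied, pairs *without* a range are frozen (δe = 0, y ≡ 1)
and pairs *with* a range obey the disjunction "unchanged OR
kcat* ∈ [kmin, kmax]", linearized as
δe ≥ (kmin−kcat)·u − M′·y and δe ≤ (kmax−kcat)·u + M′·y.  Freezing most of
the network frequently makes kcat-only engineering infeasible, so
abundances are released to [0, cap/MW] and counted instead: binaries
y_e_i = 1 pin E_i into (1±β_e)·E^wt via big-M rows, and the objective
becomes max Σ y_ij + w·Σ y_e_i.  With w = 10 > number of pairs at toy
scale, abundance changes are strictly prioritized for minimization; the
weight is a tunable preference, not a hard lexicographic order.  A range
lying entirely outside the β₂ band is logged as a warning — such a pair
can never actually move.

### Numerical choices

* **Tight big-M.**  Each indicator coefficient is min(M, tight bound
  derived from the variable bounds): |δe| ≤ kcat·(β₂−1)·u_cap with
  u_cap = min(E_i upper bound, β₂·v_max/kcat).  A uniform 10⁶ would let
  the solver's ~10⁻⁶ integrality tolerance leak ~1 flux unit through "off"
  indicators, which at toy scale is large enough to corrupt the change
  count.  The disjunction semantics are unchanged.
* **Polish LP.**  After the MILP, the binary pattern is fixed (rounded)
  and the continuous part is re-solved with *hard* band constraints,
  maximizing product flux.  Reported solutions therefore satisfy every
  constraint to LP accuracy, not MIP tolerance; unchanged pairs report
  kcat* exactly at wild type.  If the polish LP is infeasible (the
  incumbent leaned on MIP tolerances) the unpolished incumbent is kept and
  a warning logged — this has not been observed on any test instance.
* **Audit.**  `audit_strategy` re-checks the full constraint set
  arithmetically (tolerance 10⁻⁶, scale-relative where quantities are
  large) outside any solver.
* **Infeasibility diagnosis.**  On an infeasible MILP the production
  demand, growth demand and abundance band are relaxed one at a time; the
  first relaxation that restores feasibility is named in the error.
* **Ties.**  Among alternate optima the first incumbent proving optimality
  is returned; no canonical tie-break is imposed (witness enumeration is
  the oracle's job).

## Solver backends

All programs are assembled in a backend-agnostic builder.  The default
backend is HiGHS through `scipy.optimize.milp`/`linprog`; GLPK through
optlang is a second, independently implemented backend used by the test
suite to cross-check LP optima and MILP counts.  Requested feasibility
tolerance is 10⁻⁹; invariant checks allow 10⁻⁶.

## Synthetic instances and the brute-force certificate

The toy generator emulates the full ec-model structure at minimal size: an
uptake bound (10 mmol·gDW⁻¹·h⁻¹), an enzymatic chain, a branch point
feeding an enzymatic biomass drain and an enzymatic product reaction with
a free demand, unit molecular weights, and a 0.1 g/gDW pool.  The
canonical instance (chain length 1, kcats 100/100/50 h⁻¹) has closed-form
optima used as hand-derived anchors: v_bio_opt = 5 h⁻¹ and, at a 0.98
growth floor, v_pro_max = 1/15 from the pool balance
0.098 + 0.03·v_pro = 0.1.  Randomized variants (chain length 1–4, kcats
log-uniform on [10, 1000] h⁻¹, seeded, default base seed 20240 + index)
give a 20-instance family with 3–6 catalytic pairs each.

What these instances deliberately do not emulate: promiscuous enzymes at
scale, multi-subunit complexes, reversible exchange structure, realistic
molecular weights, or the degenerate alternate optima of genome-scale
networks.  Passing tests certify the *formulation and its linearization*
— that the MILP provably finds minimum-cardinality strategies under the
stated constraints — not predictive accuracy on any real host, which
additionally depends on the quality of the input ecGEM and its kcats.

The oracle certifies MILP optima by enumeration: for k = 0, 1, … and every
k-subset S of pairs it solves the LP with pairs in S ranging over the
fold-change band and all others pinned to the β₁ band.  This replaces the
indicator logic by hard intervals, which is equivalent at optimality
because a binary y_ij encodes nothing but band membership: a MILP solution
with changed set S is feasible for the S-LP, and an S-LP solution extends
to a MILP solution with y = 1 off S.  Enumeration is capped at 12 pairs
(2¹² subsets).

## Strategy evaluation

`apply_strategy` builds engineered models by substituting kcat* (or the
closest catalog prediction) for modified pairs.  `evaluate_strategy`
maximizes production subject to growth at least the strategy's achieved
growth — a floor rather than an equality, which survives float round-trip
of the stored value — and at most the strategy's number of abundance
changes outside the β_e band (abundances are re-optimized freely within
that cardinality budget).  Changes are classified by sign; a decrease
whose reaction carries < 10⁻⁶ mmol·gDW⁻¹·h⁻¹ in the engineered flux
vector is flagged knockout-replaceable.  Promiscuity is defined on the
catalytic-pair graph: an enzyme with ≥ 2 pairs over the split reaction
arms, the only operational reading available inside an ec-model.

## Known limitations

* Genome-scale runs need the published ecGEM files and benefit from a
  commercial MILP solver; the in-repo validation is desk-scale by design.
* Catalog mapping relies on a user-supplied pair→key table; live
  UniProt/EC/MetaNetX resolution is out of scope, keeping builds
  deterministic and offline.
* The oracle covers kcat modifications only; abundance-modification
  cardinality in the range-constrained mode is checked through the audit
  and self-consistency tests, not by enumeration.
* Alternate optimal strategies are not enumerated; reported strategies are
  one optimum among possibly many.
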