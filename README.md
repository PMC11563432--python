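# oko — turnover-number engineering for enzyme-constrained metabolic models

Metabolic engineering strategies are classically designed by manipulating
gene expression: knockouts, knockdowns, overexpression.  For many target
compounds — amino acids in particular — no feasible expression-level
strategy exists, because promiscuous enzymes couple reactions whose fluxes
would have to move in opposite directions.  An alternative lever is the
enzymes' *catalytic* capacity: engineering the turnover number
(k<sub>cat</sub>) of selected enzymes, or swapping in homologs from other
organisms with the desired rates, leaves the host's regulatory machinery
untouched.

`oko` implements this design problem as a mixed-integer linear program over
enzyme-constrained genome-scale metabolic models (ecGEMs, GECKO
convention).  In an ecGEM, each reaction *j* catalysed by enzyme *i*
satisfies v<sub>j</sub> = k<sub>cat</sub><sup>ij</sup> · u<sub>ij</sub>
with per-pair enzyme usages summing to abundances
Σ<sub>j</sub> u<sub>ij</sub> = E<sub>i</sub>, and total enzyme mass is
capped by the proteome pool Σ<sub>i</sub> MW<sub>i</sub>·E<sub>i</sub> ≤
σ·f·P<sub>total</sub>.

The workflow has two stages:

1. **Wild-type reference** (three LPs): maximize growth
   (v<sub>bio</sub><sup>opt</sup>); maximize product flux at optimal growth
   (v<sub>pro</sub><sup>max</sup>); then minimize total enzyme usage
   Σ<sub>i</sub> E<sub>i</sub> while retaining 98% of both optima, giving
   reference abundances **E**<sup>wt</sup>.  A variability analysis
   (min/max of each E<sub>i</sub> at fixed total usage) verifies the
   reference is essentially unique.
2. **Engineering MILP**: find the smallest set of (enzyme, reaction) pairs
   whose k<sub>cat</sub> values must change so that
   v<sub>pro</sub> ≥ f<sub>pro</sub>·v<sub>pro</sub><sup>max</sup> and
   v<sub>bio</sub> ≥ α<sub>bio</sub>·v<sub>bio</sub><sup>opt</sup>, with
   abundances held inside (1±α)·**E**<sup>wt</sup>.  Each pair carries a
   binary y<sup>ij</sup> (1 = unchanged, band half-width β₁) and the
   engineered value is confined to
   [k<sub>cat</sub>/β₂, β₂·k<sub>cat</sub>]; the bilinear term
   δ<sup>ij</sup>·E is linearized via δe<sup>ij</sup> with big-M
   constraints, and the objective maximizes Σ y<sup>ij</sup>.

A refinement restricts modified k<sub>cat</sub> values to admissible ranges
extracted from deep-learning turnover predictions across other organisms
(DLKcat/TurNup-style catalogs), freezes pairs without predictions, and
instead allows counted enzyme-abundance modifications (binaries
y<sub>e</sub><sup>i</sup>, objective Σ y<sup>ij</sup> + w·Σ
y<sub>e</sub><sup>i</sup>).  Post-processing classifies each change
(increase / decrease / knockout-replaceable), reports enzyme promiscuity,
and re-evaluates production after substituting either the optimizer's
estimates or the closest predicted values from the catalog.

Every MILP optimum at toy scale can be certified by an independent
brute-force oracle that enumerates modification subsets and solves plain
LPs — no big-M, no binaries.

## Worked example

```
$ oko toy --out toy.json
$ oko allocate --model toy.json --product P --bio-floor 0.98 --out ref.json
INFO oko: v_bio_opt=5 /h, v_pro_max=0.0666667 mmol/gDW/h, sum_e*=0.09996 mmol/gDW
```

The toy model is a three-enzyme pathway (uptake → A, then A → biomass and
A → product P) with a 0.1 g/gDW enzyme pool.  Both optima have closed
forms: the pool splits equally over the two k<sub>cat</sub> = 100 h⁻¹
enzymes of the biomass route (v_bio = 100 × 0.05 = 5 h⁻¹), and at a 0.98
growth floor the pool balance 0.098 + 0.03·v_pro = 0.1 gives v_pro = 1/15
≈ 0.0667 mmol gDW⁻¹ h⁻¹.

```
$ oko run --model toy.json --ref ref.json --f-pro 2 --alpha-bio 0.98 \
      --out strategy.json --tsv strategy.tsv
INFO oko: status=optimal objective=1 n_kcat_changed=2 n_abundance_changed=0 v_pro=0.718667 v_bio=4.9
$ cat strategy.tsv
enzyme_id  reaction_id  kcat_wt_per_s  kcat_star_per_s  fold_change  direction
E1         R1           0.02777777778  0.03492527615    1.257309942  increase
E_pro      R_pro        0.01388888889  0.1388888889     10           increase
```

Doubling product flux needs exactly two modifications: a 10-fold increase
of the product enzyme's turnover and a 1.26-fold increase upstream to free
pool capacity; growth stays at 98% of optimum.  The brute-force oracle
certifies the count and enumerates both minimal witness sets:

```
$ oko oracle --model toy.json --ref ref.json --f-pro 2 --alpha-bio 0.98
min_changes  2
witness      E1:R1;E_pro:R_pro
witness      E_bio:R_bio;E_pro:R_pro
```

Evaluating the engineered model confirms the target is met
(v_max ≥ 2 × 0.0667):

```
$ oko evaluate --model toy.json --ref ref.json --strategy strategy.json --out report.tsv
INFO oko: source=estimated v_max=0.718667 n_up=2 n_down=0 promiscuous=0.000
```

Genome-scale GECKO SBML models are imported with
`oko import --sbml model.xml --out model.json`; the range-constrained mode
runs as `oko plus ... --ranges ranges.tsv`, with ranges derived from a
predictor catalog via `oko.kcat_catalog`.

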