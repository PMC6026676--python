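# gemflux

Constraint-based analysis of genome-scale metabolic models (GEMs), focused on
how gut bacteria depend on — and shape — their nutrient environment:

* **Synthetic lethality** — single-lethal reactions and double-lethal reaction
  pairs (full bound blocking), with exchange vs. intracellular classification
  and cross-organism shared/exclusive aggregation. The pair search prunes the
  quadratic candidate space using parsimonious-FBA flux supports; results are
  contractually identical to brute-force enumeration (verified against an
  independent exhaustive oracle on every synthetic model).
* **Pathway sensitivity** — per-subsystem fraction of reactions whose flux
  changes beyond a threshold when essential or non-essential exchange
  reactions are blocked, in FBA mode (parsimonious flux vectors, absolute
  0.01 mmol/gDW/h or relative 1% thresholds) and FVA mode (flux ranges at
  ≥ 90% of each scenario's optimum).
* **Minimal-nutrient search** — starting from a state in which every
  non-essential exchange uptake is closed, re-open combinations of 1–3
  uptakes and find the minimal combinations that restore growth
  (biomass ≥ 1e-5), under aerobic and anaerobic regimes.
* **Secretion profiling** — growth-coupled maximal production/consumption
  envelope of every extracellular metabolite at fixed maximal growth under a
  minimal medium, and a cross-organism commensal/competitive interaction
  matrix.
* **Synthetic models** — deterministic toy GEMs (and a seeded random
  generator) emulating AGORA conventions (`EX_` exchanges, `c`/`e`
  compartments, biomass objective, subsystem notes), each shipped with
  brute-force ground truth so the whole pipeline is testable offline.

The LP core supports two interchangeable backends (`highs` via SciPy and
`glpk` via swiglpk) with results agreeing to 1e-6, and a parsimonious
(total-flux-minimizing) tie-break so flux comparisons are deterministic.

## CLI

```bash
# emit a toy model (SBML + ground-truth JSON)
gemflux simulate --fixture TOY-O2 --out out/
gemflux simulate --seed 7 --n-substrates 3 --out out/

# per-stage analyses; models are SBML paths or fixture names
gemflux lethality model.xml --out out/leth/
gemflux lethality TOY-O2 --remove-oxygen --out out/leth_anaerobic/
gemflux sensitivity model.xml --block R1 --block "EX_o2(e)|EX_fe3(e)" --mode fba --out sens.tsv
gemflux nutrients model.xml --regime anaerobic --k-max 2 --out combos.tsv
gemflux secretion model.xml --medium medium.tsv --anaerobic --out secretion.tsv

# cross-organism aggregation and the full pipeline
gemflux compare m1.xml m2.xml m3.xml --out compare.json
gemflux all m1.xml m2.xml --medium med1.tsv --medium med2.tsv --out results/
```

Media are 2-column TSV files (`exchange_id<TAB>max_uptake`, mmol/gDW/h) with
an optional `#anaerobic: true` header. Configuration is a YAML file
(thresholds, FVA fraction, solver, k_max); flags override file values.
Exit codes: 0 success, 2 validation error, 3 solver error, 4 infeasible model.

## Layout

```
src/gemflux/
  model.py        network types, exchange detection, medium application
  sbml.py         SBML L3+fbc (and L2 fallback) read/write
  fba.py          LP core: FBA, parsimonious tie-break, FVA, blocking, Spearman
  lethality.py    single/double lethal search + classification
  sensitivity.py  per-subsystem FBA/FVA sensitivity reports
  nutrients.py    base state + nutrient combination search
  secretion.py    growth-coupled envelopes + interaction matrix
  toys.py         fixtures, random generator, brute-force oracle
  reporting.py    deterministic TSV/JSON writers, pipeline, comparison
  cli.py          click CLI
```
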