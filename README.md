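# sulforasim

A physiology-based simulator and estimation toolkit for the conversion of
glucoraphanin (GR) to sulforaphane (SR) from broccoli products, their
gastrointestinal transit, intestinal absorption, and urinary excretion.

The core is an 18-compartment ODE model — mouth, two stomach compartments,
duodenum plus six small-intestine compartments, seven large-intestine
compartments, and blood — with:

* substrate-inhibited Michaelis–Menten hydrolysis of GR by plant myrosinase
  in the mouth, split between SR and SR-nitrile by a conversion ratio (SRR);
* first-order transit between compartments with volume-ratio bookkeeping,
  biphasic gastric emptying, and irreversible myrosinase inactivation in
  the stomach;
* first-order microbial conversion of GR to SR and to erucin/nitriles in
  the colon;
* passive SR absorption from the post-duodenal small intestine and colon
  into blood, first-order renal elimination, and cumulative urinary and
  fecal sinks so the mass balance closes exactly.

On top of the simulator the package provides trust-region least-squares
fitting of per-product parameter subsets to urine excretion-rate time
series, 90% confidence intervals and parameter correlations, one-at-a-time
sensitivity sweeps, bioavailability and cumulative-excretion computation,
and a synthetic-cohort generator (log-normal inter-individual variability
plus a power-law assay error model) for parameter-recovery studies.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (mass conservation,
fixed-step RK4 oracle equivalence, structural checks, qualitative kinetics,
sensitivity directions, parameter recovery, error-model calibration, and
confidence-interval machinery). A few recovery assertions are expected to
fail by design: the 5- and 7-parameter fitting recipes are practically
non-identifiable from a single 6–15 point series (the colonic transit
constant trades off against the other rate constants at below 1e-5 relative
curve change), which reproduces the very wide confidence intervals the
reference analysis reports for those products.

## CLI

```sh
# forward-simulate a packaged product fixture
sulforasim simulate --product HighBP --t-end 1600 --out curve.csv

# generate a synthetic cohort (datasets.csv + truth.csv + manifest)
sulforasim synth --product MedBF --n 15 --seed 42 --out cohort/

# fit the product's default parameter subset to every matching series
sulforasim fit --data cohort/datasets.csv --product MedBF --out fits/

# one-at-a-time sensitivity sweep
sulforasim sensitivity --product HighBP --param srr --range 0.1:0.5:5 --out sens/

# parity r^2, bioavailability and estimate summaries from a fit table
sulforasim report --data cohort/datasets.csv --fits fits/fits.csv \
    --product MedBF --out report.json
```

Product fixtures (`HighBP`, `HighBF`, `MedBF`, `LowBF`, `NoBF`) ship with
the package, including the reduced alternate initial-SR loadings for
`MedBF`/`LowBF` (`--reduced-itc0`). Parameter files are YAML mappings of
flat symbol names (`srr`, `k_tsi`, `v_blood`, ...) over a product fixture.

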