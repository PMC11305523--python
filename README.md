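# obesim

Forward-time simulation of what happens to a highly polygenic BMI trait when
the strong negative selection pressure exerted by childbirth mortality is
suddenly relaxed, together with the ecological cross-country statistical
pipeline used to probe the association between historical lifetime maternal
death rates (LMDR) and present-day obesity rates, and seeded synthetic-data
generators so every stage is testable without external downloads.

## Components

| module              | what it does |
|---------------------|--------------|
| `obesim.polygenic`  | additive many-locus architecture: allele frequency → mean BMI, BMI variance, obesity prevalence (normal approximation) |
| `obesim.selection`  | mortality schedules → obese/non-obese fitness differentials; gain/loss balance recursion on the allele pool |
| `obesim.simulate`   | deterministic and Wright–Fisher trajectories across an obstetrics-transition event; birth-cohort mixing into adult prevalence by calendar year |
| `obesim.stats`      | log transforms, Pearson/Spearman correlation matrices, residual-method partial correlation, OLS + partial-F stepwise regression, median splits, exponential fits, Fisher-z comparison, 2×2 MMR/obesity contingency analysis |
| `obesim.synth`      | seeded generators: country tables with planted effects and target log-scale correlations, contingency fixtures, population genotype/phenotype samples |
| `obesim.io` / `obesim.cli` | CSV/TSV/JSON boundary, run metadata, `obesim` command-line interface |

## CLI

```bash
# forward-time trajectory from a YAML config (TSV + metadata JSON out)
obesim simulate --config examples/relaxation.yaml --out-dir out/sim

# synthetic country table (CSV + generator-spec echo)
obesim synth --seed 1 --out-dir out/synth

# full statistical bundle on a country CSV: correlation matrices, partial
# correlation, OLS + stepwise regression, median-split re-analysis,
# exponential fits, contingency analysis
obesim analyze --input out/synth/countries.csv --out-dir out/analysis
```

`analyze` flags: `--controls`, `--median-split-var`, `--mmr-threshold`
(default 500 per 100,000), `--obesity-threshold` (default 19.5%), `--subset`
(development-class restriction for the contingency analysis), `--seed`,
`--log-level`.

Country CSVs use the printed units of the source tables: LMDR and obesity in
percent, MMR per 100,000 live births, neonatal mortality per 1,000. Cells
written as `<0.01` are treated as below-detection and handled by the
log-transform floor rule (non-positive values are floored at half the
smallest positive observed value before logging).

## Notes

- Two reproductive-output conventions are available (`terminal`: maternal
  death forfeits all output; `midpoint`: death halfway through reproduction);
  the default is `terminal`.
- The dosage convention defaults to `haploid_accounting` (one counted allele
  slot per locus), which reproduces the headline arithmetic
  1000 loci × 0.1 kg/m² × 5% shift = 5 kg/m²; `diploid` doubles the shift.
- The stabilizing gain is calibrated so the pre-transition schedule is
  stationary unless overridden in the config.
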