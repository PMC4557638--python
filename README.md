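# euireclass

Reclassification of external-cause deaths coded as **events of undetermined
intent** (EUI, ICD-10 Y10–Y34) into non-transport accidents (W00–X59),
suicides (X60–X84), and homicides (X85–Y05, Y08, Y09).

The pipeline:

1. **records_io** — death-record data model, ICD-10 external-cause grouping,
   the 19-category nature-of-injury mapping (S/T codes), CSV I/O, and
   dummy-coding of the ten categorical covariates ("unknown"/"unspecified"
   are ordinary levels, never imputed).
2. **synthetic_data** — seeded microdata generator with known ground truth:
   cause-conditional covariate distributions and a configurable masking rule
   that relabels true-cause deaths as EUI (uniform, covariate-modulated, or
   hidden-homicide scenarios).
3. **mlogit_core** — sex-stratified, class-weighted multinomial logistic
   model fitted by a deterministic Newton optimizer; estimated
   classification probabilities (ECPs) per record; a binary
   transport-accident discriminator.
4. **reclassifier** — threshold assignment (argmax ECP ≥ ECP₀ over the grid
   {0, 0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9}), predicted×actual class
   matrices with relative errors and agreement shares, the row-normalized
   misclassification matrix P, the population-level adjustment
   U_j^Adj = Σ_i P_ij·U_i, and two comparators (sex/age-proportional and
   fuzzy proportional-sharing redistribution).
5. **bootstrap** — coefficient-perturbation stability check
   (B̃ = B + SE·γ, γ ~ N(0,1), 250 replicates by default).
6. **rates** — age-standardized death rates per 100,000 against the bundled
   European standard population, with official / EUI-contribution /
   adjusted variants and the reclassified share of the adjusted rate.

## CLI

```bash
# full pipeline on 50k synthetic records, all artifacts into out/
euireclass all --n 50000 --seed 1 --out out/

# or stage by stage
euireclass generate --n 50000 --seed 1 --out data/
euireclass fit        --input data/microdata.csv --out models/
euireclass evaluate   --input data/microdata.csv --model models/model_male.json \
                      --sex male --out eval/
euireclass reclassify --input data/microdata.csv --model models/model_male.json \
                      --sex male --out reclass/
euireclass adjust     --input data/microdata.csv --model models/model_male.json \
                      --sex male --ecp0 0 --out adj/
euireclass bootstrap  --input data/microdata.csv --model models/model_male.json \
                      --sex male --replicates 250 --out bs/
euireclass rates      --official official.csv --contribution eui.csv \
                      --population pop.csv --out rates/
```

`all` writes microdata, truth table, per-sex model JSON, evaluation
summaries and class/misclassification matrices over the ECP₀ grid, EUI
distributions (threshold, population-adjusted, comparators), rate tables,
bootstrap reports, and a reproducibility manifest. Identical config + seed
gives byte-identical CSV output.

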