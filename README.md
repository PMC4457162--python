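# aposcan

Warning-signal honesty analysis pipeline: model beetle coloration through an
avian predator's visual system, quantify toxicity from *Daphnia* bioassays,
and relate conspicuousness to toxicity and to field predation survival —
testable end to end on synthetic data with known ground truth.

## What's inside

| Module (`aposcan.*`)   | Purpose |
| ---------------------- | ------- |
| `synthetic`            | Generators for every pipeline input: smooth reflectance spectra, raw 4-channel camera image pairs with grey standards, binomial dose–response bioassays (7 dilutions × 10 animals × 1/3/24 h), and interval-checked field predation records (4 h checks over 48 h). Pure functions of their seed. |
| `calibration`          | Power-law linearisation against 2–99% grey standards, normalisation to the in-frame 40% standard, polygon region measurement. |
| `cone_mapping`         | True quantum catches (trapezoidal ∫R·I·S, perfect-reflector normalised, D65 default) and the degree-1/2/3 polynomial mapping from camera channels (peaks 366/465/522/667 nm) to viewer cone catches, with per-receptor R². |
| `colour_metrics`       | Tetrahedral colour space (regular tetrahedron, circumradius 0.75, UV on +z), saturation, double-cone luminance, shoelace pattern area. |
| `discriminability`     | Receptor-noise-limited log-ratio contrasts (chromatic ΔS via the general quadratic form, achromatic ΔL), background contrast, internal elytra-vs-spot luminance contrast, JND classification. |
| `toxicity`             | 3 h mean-mortality summary (`ln(mean + 1)`), ML logistic/probit LC50 with delta-method CI, control-group comparison. |
| `survival`             | Kaplan–Meier (first principles, Greenwood variance), Cox PH with Breslow ties and block stratification (first-principles Newton solver), pairwise contrasts, exact-CI attack rate. |
| `honesty`              | Headline models: toxicity ~ species + size + weight + luminance + saturation + area + contrasts (+ species×contrast, saturation×contrast), backward-AIC simplified; within-species saturation test; leave-one-species-out robustness; attack ~ conspicuousness (logistic + Cox cross-check). |
| `model_design`         | Artificial-prey colour grids around a target catch, JND-minimising match selection, UV-printability advisory. |
| `pipeline`             | End-to-end glue: world → images → calibration → mapping → metrics → JNDs → toxicity → honesty fit. |

Default viewer: blue-tit-like cone set built from peak-parameterised pigment
templates with oil-droplet long-pass filtering (packaged as
`aposcan/data/viewer_cones.csv`, replaceable), relative cone abundances
UV 0.37 / SW 0.70 / MW 0.99 / LW 1.00, Weber fraction 0.05.

## CLI

```bash
aposcan simulate --config world.cfg --out study/ --images
aposcan calibrate --images study/images --out measurements.csv
aposcan map --model mapping.json --fit
aposcan map --model mapping.json --measurements measurements.csv --out catches.csv
aposcan metrics --catches catches.csv --out metrics.csv
aposcan jnd --catches catches.csv --specimens study/specimens.csv --out jnd.csv
aposcan toxicity --records study/bioassay.csv --out toxicity.csv
aposcan survival --records study/predation.csv --out-curves km.csv --out-model cox.json
aposcan honesty --table specimen_table.csv --report report.json
aposcan design --target target.csv --out design.json
aposcan pipeline --config world.cfg --out run/   # everything at once
```

`world.cfg` is YAML, e.g.:

```yaml
seed: 1
honesty_slope: 0.5        # toxicity change per JND of chromatic contrast
hazard_coefficient: 0.05  # log-hazard drop per JND for field models
n_per_species: 36
```

## Conventions worth knowing

- All tests are two-sided; predictors are z-scored; species are sum-coded,
  so the contrast main effect is the average within-species slope.
- Block (transect) heterogeneity is handled by Cox stratification, not a
  random effect; ambiguous field withdrawals (rodent/degraded/slime) are
  excluded by default.
- The toxicity log transform is `ln(mean dead at 3 h + 1)`; LC50 is
  reported but never consumed by the honesty stage.
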