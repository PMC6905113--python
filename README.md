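# tariffva

Tariff-method verbal autopsy: training, cause prediction, out-of-sample
validation, and dataset-robustness analysis.

In populations where most deaths occur outside health facilities, the
cause of death is often inferred from a **verbal autopsy** (VA): a
structured interview with the family about the signs and symptoms
preceding death. The Tariff method is an empirically derived algorithm
for assigning a cause to each VA from a training database of
**gold-standard deaths** — deaths whose true cause was established from
medical records under strict ex-ante criteria. This package is for
biostatisticians and VA methods researchers who want to train Tariffs
on gold-standard data (real or synthetic), validate them the standard
way, and quantify how stable the cause-symptom relationship is when a
second dataset is pooled with the first.

## The method

For symptom *i* and cause *j*, with `x[i,j]` the fraction of cause-*j*
deaths endorsing symptom *i* (don't-know counts in the denominator
only):

```
Tariff[i,j] = (x[i,j] − Median_i) / IQR_i
```

with the median and interquartile range taken across causes. Tariffs
are tested for significance by a stratified bootstrap (default 500
resamples within cause, 99% percentile intervals; pairs whose interval
touches zero are removed) and rounded to the nearest 0.5. A record's
score for a cause is the sum of the cause's rounded Tariffs over the
record's endorsed symptoms; the predicted cause is the argmax.

Validation follows the standard VA design: repeated train/test splits
in which the test set is resampled to a cause composition drawn from a
Dirichlet distribution, scored by chance-corrected concordance (CCC,
individual level), CSMF accuracy (population level), and
chance-corrected CSMF accuracy (CCCSMF, 0 = chance). The robustness
analysis refits Tariffs on a pooled dataset A∪B and reports significance
retention, direction flips, the largest Tariff changes, and metric
deltas.

## Worked example

```python
import tariffva as tv

# synthetic gold-standard neonate dataset mirroring the published
# combined cause composition (stillbirth dominant, six causes)
spec = tv.phmrc_like_spec("neonate", scale=0.2, seed=1)
ds = tv.generate(spec)
print(f"{ds.n_records} deaths, {len(ds.causes)} causes, {len(ds.symptom_ids)} symptoms")

tm = tv.fit(ds, cfg=tv.BootstrapConfig(n_reps=200, seed=1))
print(f"significant tariffs: {int(tm.significant.sum())} / {tm.significant.size}")

rep = tv.run_validation(
    ds,
    vcfg=tv.ValidationConfig(n_splits=20, seed=1),
    bcfg=tv.BootstrapConfig(n_reps=200, seed=1),
)
m, lo, hi = rep.csmf_accuracy
print(f"CSMF accuracy: {m:.3f} (95% UI {lo:.3f}, {hi:.3f})")
m, lo, hi = rep.cccsmf_accuracy
print(f"CCCSMF accuracy: {m:.3f} (95% UI {lo:.3f}, {hi:.3f})")
m, lo, hi = rep.per_cause_ccc["Stillbirth"]
print(f"CCC Stillbirth: {m:.1f}% (95% UI {lo:.1f}, {hi:.1f})")
```

prints

```
663 deaths, 6 causes, 18 symptoms
significant tariffs: 26 / 108
CSMF accuracy: 0.814 (95% UI 0.687, 0.957)
CCCSMF accuracy: 0.495 (95% UI 0.149, 0.883)
CCC Stillbirth: 31.6% (95% UI -8.6, 87.0)
```

Reading the numbers: 26 of the 108 cause-symptom pairs carry a Tariff
whose sign is bootstrap-certain; across 20 Dirichlet-resampled test
sets the estimated cause fractions are 81% accurate relative to the
worst case (CSMF accuracy 0.814), which is well above chance (CCCSMF
0.495 > 0); individual-level agreement for stillbirth is modest at this
small training scale (CCC 31.6%), with a wide uncertainty interval, as
expected for six highly confusable neonatal causes.

The same workflow is available from the shell:

```sh
tariffva simulate --module neonate --scale 0.2 --seed 1 --out gs.csv --schema-out schema.yaml
tariffva fit      --data gs.csv --schema schema.yaml --module neonate --out tariffs.csv
tariffva predict  --data gs.csv --schema schema.yaml --module neonate --tariffs tariffs.csv --out pred.csv
tariffva validate --data gs.csv --schema schema.yaml --module neonate --splits 20 --out metrics.csv
tariffva compare  --data-a gs.csv --data-b other.csv --schema schema.yaml --module neonate --out-prefix cmp
```

See `docs/methods.md` for the model's assumptions, the validation
design, numerical conventions, and known limitations.

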