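# readerbias

When a medical-imaging dataset is split among several readers for annotation
without a consensus step, the resulting labels carry each reader's errors:
random slips, and systematic biases such as consistently over-calling
(false-positive labeling) or under-calling (false-negative labeling) disease.
`readerbias` is a simulation pipeline for quantifying what those label errors
do to a binary image classifier, and how much a label-free consistency
regularizer mitigates them. It is aimed at researchers designing multi-reader
annotation protocols or evaluating label-noise-robust training.

The pipeline:

1. **Generate** a seeded two-class grayscale dataset (shared noisy background;
   class 1 adds soft Gaussian opacities), or point the tools at any image
   directory with a CSV label manifest.
2. **Inject** label errors at a controlled overall level *p*: `random`
   (flip a *p*-fraction of each class), `false_positive` (flip a
   *2p*-fraction of negatives), or `false_negative` (flip a *2p*-fraction of
   positives). Counts are exact and sampled without replacement; the test
   split is never touched.
3. **Train** a small CNN with plain cross-entropy (baseline) or with
   cross-entropy plus paired softmax divergence regularization (improved):

       L = L_CE + α · mean_t KL( f(x′_t;θ) ‖ f(x″_t;θ) )

   where x′, x″ are two independent random flip-augmentations of the same
   training image. The KL term never consults the labels, so it cannot be
   misled by them.
4. **Evaluate** test AUC (Mann–Whitney form, tie-exact) over the full
   bias-type × level × model × repetition grid, resumably.
5. **Analyze** the decline: per-type OLS slope of AUC on error level
   (percentage points) and the homogeneity-of-slopes ANCOVA F-test of
   whether the three bias types degrade AUC at the same rate.

## Worked example

```python
from readerbias import BiasSpec, DatasetSpec, error_report, inject_bias
from readerbias.synthetic import manifest_rows

manifest = manifest_rows(DatasetSpec())          # 500/500 train, 109/109 val, 234/390 test
spec = BiasSpec("false_positive", overall_level=0.05, seed=42)
print(error_report(inject_bias(manifest, spec)))
```

prints

```
       fp_count  fn_count   fp_rate  fn_rate  overall_error_rate
split
train        50         0  0.100000      0.0            0.050000
val          11         0  0.100917      0.0            0.050459
test          0         0  0.000000      0.0            0.000000
```

— at a 5% overall introduced-error level, the false-positive scheme flips
exactly 10% of the negative labels (50 of 500 in the training split), no
positives, and leaves the test split clean. The same construction at 25%
flips half the negatives; `random` at 15% flips 15% of each class.

The full desk-scale experiment, from the shell:

```bash
readerbias generate --out data --config examples/dataset.yaml
readerbias experiment --data data --config examples/experiment.yaml --out results
readerbias summarize --records results/records.csv --out results/summary.csv
readerbias analyze --records results/records.csv --out results/slopes.csv
```

`analyze` emits one AUC-per-percentage-point slope per (model, bias type)
plus the per-model interaction F-test. On the built-in synthetic conditions
(200 training images/class, levels {0, 10%, 25%}, 3 repetitions) the
baseline's slopes are steeper than the regularized model's for every bias
type — e.g. −0.0071 vs −0.0062 AUC per point under random error, −0.0060 vs
−0.0049 under false-negative bias — while the slope differences *between*
bias types are not significant for either model (interaction p ≈ 0.4).
Exact values are reproduced by `tests/test_acceptance.py`.

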