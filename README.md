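# casmi

Feature selection for categorical data by **coverage-adjusted standardized
mutual information** (CASMI), built for the small-sample regime typical of
health and biomedical datasets: many categorical features (diagnoses,
genotypes, coded clinical notes), one categorical outcome, and far fewer
observations than the feature spaces would need for plug-in
information-theoretic methods to behave.

## The method

For a feature *X* and outcome *Y* on finite alphabets, the score is

```
κ*(X, Y) = κ(X, Y) · (1 − π₀(X))ᵘ ,      κ(X, Y) = MI(X, Y) / H(Y)
```

where κ is standardized mutual information (1 ⇔ Y is determined by X,
0 ⇔ independence) and 1 − π₀ is the sample coverage of X — the population
probability mass of the categories actually observed — estimated by
Turing's formula 1 − N₁/n (N₁ = number of categories seen exactly once).
The coverage factor is what separates genuinely informative,
well-observed features from features that merely *look* predictive
because most of their categories were seen once (an ID-like column is the
extreme case: coverage 0, score 0).

Two estimation choices matter at small n:

* **Entropies** are estimated not by the plug-in (maximum-likelihood)
  estimator, whose negative bias decays only like 1/n, but by a
  bias-corrected estimator Ĥz whose bias decays exponentially in n:

  ```
  Ĥz = Σᵥ₌₁ⁿ⁻¹ (1/v) · n^(1+v) (n−1−v)!/n! · Σₖ p̂ₖ Πⱼ₌₀^(v−1) (1 − p̂ₖ − j/n)
  ```

  evaluated factorial-free through a telescoping product (see
  `docs/methods.md`).

* **Screening** uses the fact that under independence
  2n·MÎz + (K₁−1)(K₂−1) is asymptotically chi-squared with
  (K₁−1)(K₂−1) degrees of freedom (K₁, K₂ = observed cardinalities), giving
  a calibrated per-feature independence test.

Selection then runs in two stages: (1) drop every feature whose
independence test fails to reject at level α (default 0.10); (2) greedily
grow a **joint feature** — at each step adjoin the candidate maximizing
κ̂* of the joint with the outcome, stopping as soon as the best candidate
no longer increases the score. Scoring the joint handles redundancy
automatically (a redundant feature adds no MI but lowers coverage) and
the number of selected features is learned from the data rather than
supplied by the user.

Six classical plug-in criteria (MIM, JMI, CMIM, MRMR, DISR, NJMIM) are
included for comparison, along with an exactly enumerable benchmark
generator and the **Information Recovery Ratio**
IRR = MI(X_selected, Y)/MI(X_relevant, Y) computed on the exact model.

## Worked example

```python
from casmi import SimConfig, build_true_joint, generate_benchmark, irr, select_features

table = generate_benchmark(SimConfig(n=800, seed=7))   # 10 features, outcome Y
result = select_features(table, alpha=0.10, u=1.0)
for name, score in zip(result.selected, result.trajectory):
    print(f"  + {name:4s} -> {score:.4f}")
print(f"automatic stop after c={result.c} features")

report = irr(build_true_joint(), result.selected)
print(f"information recovery ratio: {report.irr:.4f}")
```

prints

```
  + X3   -> 0.1761
  + X2   -> 0.3641
  + X5   -> 0.5889
  + X1   -> 0.6910
automatic stop after c=4 features
information recovery ratio: 0.8027
```

The greedy search adds X3, X2, X5, X1 — the CASMI score of the growing
joint feature rising at each step — then stops: at n = 800 the remaining
relevant feature (X4, with its redundant copy X6) is too weakly observed
for its estimated contribution to survive the coverage penalty, so the
selected set recovers 80.3% of the outcome-relevant information. At
n ≥ 1500 the same pipeline recovers all of it (IRR = 1).

The scripts in `examples/` walk through each capability: estimator bias
(`entropy_bias.py`), the selection pipeline (`select_features.py`),
baseline comparison (`compare_baselines.py`) and preprocessing
(`preprocess_table.py`). A thin CLI mirrors the library:

```bash
casmi simulate --n 1500 --seed 7 --out data.csv
casmi select --input data.csv --outcome Y --out report.json
casmi baseline --input data.csv --outcome Y --method mrmr -k 5
casmi evaluate --experiment irr --reps 200 --sizes 500,1500 --seed 7
```

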