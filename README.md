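# firthiss

Tools for handling **separation** in logistic regression — and for judging
whether "bring more data" is good advice when it happens.

## The problem

In small or sparse data sets with a binary outcome, the maximum-likelihood
(ML) estimate of a logistic regression coefficient may not exist: when a
covariate or a linear combination of covariates perfectly predicts the
outcome for some (*quasi-complete*) or all (*complete*) observations, the
estimate diverges to ±∞. The simplest case is a 2×2 table with a zero cell.
Two remedies are commonly recommended:

* **Firth's correction (FC)** — maximize the penalized likelihood
  l(β) + ½ log det I(β) (the Jeffreys-prior penalty), which removes the
  first-order bias of ML and always yields finite estimates. For a 2×2 table
  it equals ML after adding ½ to every cell.
* **Increasing the sample size (ISS)** — keep collecting observations from
  the same population until the separation disappears, then fit as usual.

This package implements both, plus the machinery to compare them: an
LP-based separation detector, profile penalized-likelihood confidence
intervals for FC, Wald intervals for ML, a synthetic data generator
emulating a realistic epidemiological covariate structure (10 correlated
mixed-type covariates; an unbalanced binary exposure with E(x₁) = 0.8 as the
estimand's covariate), and a full-factorial Monte-Carlo study over
K ∈ {2, 5, 10} covariates, N ∈ {80, 200, 500}, event rates E(Y) ∈ {0.1, 0.25}
and true effects β₁ ∈ {0, 0.35, 1.39, 2.77}. Strategies are scored by bias,
MSE, coverage, power, CI width, the mean escalated sample size N̄new, and the
**cost-adjusted relative efficiency**

```
CARE = (MSE_ML+ISS · N̄new) / (MSE_FC · N),
```

which charges the ISS strategy for the extra observations it consumed;
CARE > 1 means FC at the original sample size is the more efficient use of
data.

## A worked example

A 2×2 table with no events among the exposed (`examples/fit_2x2_separated.py`):

```python
import firthiss as fi

d = fi.dataset_from_2x2(20, 10, 4, 0)        # f_yx counts, empty (y=1, x=1) cell
fi.detect_separation(d).kind                  # 'quasi-complete'
fi.ml_fit(d).estimate_exists                  # False — ML diverges
fc = fi.firth_fit(d)
fi.profile_penalized_ci(d, fc, j=1)
```

prints

```
separation: quasi-complete
ML estimate exists: False
Firth log OR for exposure: -1.528  (95% profile CI -6.45 to 0.85)
closed form (ML on counts + 0.5): -1.528
```

The Firth log odds ratio is finite and matches the add-½ closed form; the
profile interval is asymmetric, reflecting how little the data say about the
exposed-group event probability.

The other scripts in `examples/` show the separation detector on hand-built
datasets, a single "bring more data" replication (`iss_single_replication.py`),
and a miniature three-scenario slice of the factorial study
(`mini_simulation.py`).

A thin CLI covers the CSV use case:

```bash
firthiss check-separation data.csv -y outcome
firthiss fit data.csv -y outcome --method firth --ci profile
firthiss simulate -c grid.yaml -o results.csv --summary summary.json
```

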