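# qpref

Q-methodology for multivariate stimuli: forced-distribution Q-sort data,
dominance statistics, by-person factor analysis, and a five-analysis
protocol separating *what people prefer* from *what they pay attention to*.

## The problem

In a Q-sort experiment, participants rank-order a set of stimuli into a
fixed quasi-normal grid (e.g. 32 stimuli over ranks −5 … +5 with slot
counts 1, 2, 3, 3, 4, 6, 4, 3, 3, 2, 1).  When the stimuli are built from a
factorial design — say handheld objects varying in Size × Texture ×
Contour × Behavior — two distinct questions arise:

* **Preference**: within a variable, which level is liked more
  (smooth over rough texture)?
* **Dominance**: across variables, which variable drives the ranking
  (does texture matter more than size)?

`qpref` quantifies dominance from the spread of a variable's levels across
the grid.  For variable *v* with levels *l₁ … lₙ* and per-stimulus scores
*s*:

* raw dominance *D_v* = max over level pairs of |Σ s(lᵢ) − Σ s(lⱼ)|
  = max level sum − min level sum;
* weighted dominance *WD_v* = *D_v* / (2 × top-⌊N/n⌋ grid-slot sum), the
  largest difference the grid allows for an *n*-level variable, so
  variables with different level counts are comparable (0 ≤ WD ≤ 1 for
  balanced designs);
* comparable score difference *CSD_v* = *WD_v* × mean over variables of
  their attainable maxima (back in rank-sum units);
* proportion of dominance *PD_v* = *WD_v* / Σ *WD*, a per-person
  attention-weight profile summing to 1.

Around this sit the protocol's five analyses: (1) a pooled ordered-probit
model of overall preference with Wald tests per variable and
likelihood-ratio diagnostics of the proportional-odds and constant-scale
assumptions; (2) OLS/ANOVA of the dominance weights; (3) by-person factor
analysis (PCA of the participant correlation matrix, varimax rotation,
automatic flagging of defining sorts, loading-weighted factor scores) with
per-cluster factor-score ANOVAs and per-cluster dominance; (4) an
ordered-probit model of the stacked per-cluster score profiles with
variable × cluster interactions; (5) the dominance-weight model with
variable × cluster interactions on the flagged participants.

## Worked example

The bundled `qpref.worked_example` module carries the published summary
tables of an 18-participant study of 32 interactive objects.  Comparing
each participant's dominance weights across the four design variables:

```python
import qpref
from qpref import worked_example

weights = worked_example.participant_weights()   # 18 x 4 PD weights
coef, anova = qpref.weights_anova(weights)
print(coef.round(3).to_string(index=False))
```

```
     term  estimate    se     t     p
Intercept     0.131 0.033 3.994 0.000
  Texture     0.091 0.046 1.971 0.053
  Contour     0.012 0.046 0.264 0.792
 Behavior     0.373 0.046 8.064 0.000
```

The intercept is the mean attention weight on the reference variable
(Size, 0.13); the Behavior coefficient says participants put on average
0.37 *more* of their attention on the objects' autonomous behavior than on
their size — behavior dominates the decision.  The accompanying ANOVA
(`anova`) shows the between-variables effect: F(3, 68) = 28.3, p < 0.001.

The per-cluster ANOVAs of the third cluster's factor scores tell the same
story at cluster level — only Behavior structures that cluster's ranking:

```python
scores = worked_example.factor_grid_scores()     # 32 stimuli x 3 factors
design = worked_example.io_design()
table = qpref.factor_score_anova(scores, design)
print(table[table.factor == "F3"].round(3).to_string(index=False))
```

```
factor variable  df1  df2      F     p  degenerate
    F3     Size    1   30  0.075 0.786       False
    F3  Texture    1   30  0.170 0.683       False
    F3  Contour    1   30  0.691 0.413       False
    F3 Behavior    3   28 59.802 0.000       False
```

## Command line

```sh
qpref simulate --out-dir study --seed 4        # synthetic study files
qpref validate study/data.csv --design study/variables.csv
qpref dominance study/data.csv study/variables.csv
qpref factors study/data.csv -k 3 --out-dir study/fa
qpref protocol study/data.csv study/variables.csv -k 3 --out-dir study/out
```

`protocol` runs all five analyses and writes every coefficient, test and
score table as CSV plus a `Qfact.txt` factor-count criteria report.

## Raw study data

The worked study's raw individual sorts are distributed with the original
article's supplementary material (OSF: <https://osf.io/pzvfb>) and are not
redistributed here.  `qpref.packaged_fixture()` loads them when a
downloaded `data.csv` path is supplied (the tests look under
`data/worked_study/`), and otherwise generates a clearly-labelled
synthetic stand-in with the same design, grid and cluster structure.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it regenerates the synthetic study, runs the full five-analysis
protocol on it, re-runs the printed-input analyses of the worked example,
and writes its JSON result file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
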