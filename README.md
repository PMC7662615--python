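# audiobn

Bayesian-network analysis of hearing loss in working populations:
audiometric loss indexing, a discrete Bayesian network over gender, age
group, family history and binaural-loss group with exact scenario
inference, and cross-validated per-group ROC/AUC — plus a synthetic cohort
generator calibrated to published occupational-health summary tables, so
the whole pipeline is testable without access to raw worker records.

It is written for epidemiologists and occupational-health researchers who
want to quantify how demographic and hereditary factors shift the
probability of noise-induced hearing loss, and to audit every step of that
computation.

## The model

**Loss indexing.** Hearing acuity is summarized by the "social" binaural
loss index used for disability assessment. Per ear, from pure-tone
thresholds at 500/1000/2000/3000 Hz (dB HL):

```
monaural = (mean(t500, t1000, t2000, t3000) − 25) × 1.5     clamped to [0, 100]
binaural = (5 × better_ear + worse_ear) / 6
```

The binaural percentage is discretized into five groups: group 1 is
exactly 0 % (no measurable loss), then (0, 15], (15, 30], (30, 45] and
\> 45 %. Age is discretized into quintiles (<29, 29–34, 35–39, 40–48, ≥49
years); family history of hearing problems is a No/Yes flag.

**The network.** A discrete Bayesian network factorizes the joint as
p(x₁,…,xₙ) = ∏ᵢ p(xᵢ | πᵢ) over a DAG. The canonical study topology has
the three predictors as parentless parents of the loss group —
86 free parameters instead of the 99 of the unrestricted joint. CPTs are
fitted by maximum likelihood (optionally Laplace-smoothed); posteriors
under any evidence are computed exactly by sum–product variable
elimination; structure can alternatively be learned by BIC-scored greedy
hill climbing with seeded random restarts.

**Validation.** Per loss group, a one-vs-rest classifier scores each
worker with the posterior probability of that group; 10-fold
cross-validated AUC (Mann–Whitney rank form with midrank tie handling) is
reported per fold and pooled over the joined held-out predictions.

## Worked example

```python
from audiobn import HearingLossModel, default_generating_model, sample_cohort

cohort = sample_cohort(default_generating_model(), n=100_000, seed=42,
                       with_audiograms=True)
res = HearingLossModel(cohort).fit()
print(res.summary())
```

```
                     Hearing-loss Bayesian network
========================================================================
No. observations:     100000    Laplace alpha: 0
Free parameters:          86    BIC: -272387.01
Edges: gender->loss_group, age_group->loss_group, family_history->loss_group
------------------------------------------------------------------------
Loss-group distribution by single predictor (percent):

  gender
    baseline: 89.08, 9.80, 1.06, 0.06, 0.00
       Women: 95.14, 4.71, 0.15, 0.00, 0.00
         Men: 88.18, 10.56, 1.19, 0.07, 0.00
  ...
```

Each row is the fitted conditional distribution over the five loss groups
(group 1 first). The baseline 89.08 % is the model's marginal probability
of no measurable loss; women reach group 1 far more often (95.14 %) than
men (88.18 %), and the age gradient is the steepest effect. A scenario
query under full evidence:

```python
post = res.predict({"gender": "Men", "age_group": ">=49",
                    "family_history": "Yes"})
print((100 * post).round(2))
#  1    72.35
#  2    24.79
#  3     2.64
#  4     0.22
#  5     0.00
```

i.e. a man aged 49+ with a family history of hearing problems has a 72 %
probability of no measurable loss — some 17 points below the baseline.
Cross-validation (`res.cross_validate(k=10, seed=42)`) pools the held-out
posteriors and yields per-group AUCs of 0.72/0.70/0.84/0.79 for groups
1–4 here (group 5 is flagged undefined: at its generating prevalence of a
few per 100,000 no case was drawn).

The same pipeline runs from the shell:

```bash
audiobn simulate --n 10000 --seed 1 --out cohort.csv
audiobn index --audiograms audiograms.csv --out indexed.csv
audiobn fit --cohort cohort.csv --out net.json
audiobn query --net net.json -e gender=Women -e age_group='<29'
audiobn scenarios --net net.json --by family_history,gender,age_group --out table.csv
audiobn validate --cohort cohort.csv --k 10 --seed 1 --out auc.json
audiobn run --seed 1 --out-dir run1        # the whole thing, stamped + logged
```

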