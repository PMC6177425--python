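# rxvar — small-area variation in first-time drug prescription

`rxvar` quantifies how incident (first-time) drug prescribing varies across
geographic units, for pharmacoepidemiologists and health-services
researchers working with claims data. It implements, end to end:

1. **A national incidence model per drug.** Person-years after a two-year
   washout are binned by 5-year age band, calendar year, incident-
   prescription count *r*, and incident-year count *m*; first use of drug
   *d* in bin *b* is modelled by discrete-time survival logistic regression
   (dummy-coded bins, all pairwise interactions, ridge penalty tuned by
   cross-validation), with a person-level holdout verifying unbiased
   prediction.

2. **A signed drug–county deviance.** With national bin weights
   w<sub>d,b</sub> = n<sub>d,b</sub>/Σ<sub>b'</sub>n<sub>d,b'</sub>,
   county counts are population-standardized
   (n<sub>d,c</sub> = Σ<sub>b</sub> w<sub>d,b</sub>n<sub>d,b,c</sub>, same
   for y) and compared with the model expectation
   ŷ<sub>d,c</sub> = Σ<sub>b</sub> w<sub>d,b</sub>n<sub>d,b,c</sub>p̂<sub>d,b</sub>
   through the signed root binomial deviance

   G<sub>d,c</sub> = sign(y−ŷ)·[y·log(y/ŷ) + (n−y)·log((n−y)/(n−ŷ))]<sup>1/2</sup>

   (no factor of 2 inside the bracket — see `docs/methods.md`). Positive G
   means the county uses the drug more than its population mix predicts.

3. **Analyses of the deviance matrix.** PCA via SVD with leave-class-out
   stability; CCA against county demographics with Wilks/Rao-F and
   permutation significance; county-pair distance correlations and a
   border same-state regression; therapeutic-class recovery via an adapted
   Adjusted Rand procedure with a permutation null; state-group rank-sum
   tests; elastic-net cross-prediction with drug-set coefficient tests; and
   per-county brand-vs-generic preference with a demographic model of it.

Because claims data at this granularity are proprietary, the package ships
a first-class **synthetic claims generator** with planted ground truth
(latent county components, class-county effects, state offsets, brand
preferences, drug-county odds offsets), so every stage is testable and
every estimator's calibration and power can be measured. A deviance matrix
from real data in the same CSV shape can be dropped in from the components
stage onward.

## Worked example

The analysis is a sequence of numbered drivers over one run directory:

```bash
python analysis/01_simulate.py          --seed 1 --out results/run
python analysis/02_cohort.py            --seed 1 --out results/run
python analysis/03_fit_national_model.py --seed 1 --out results/run
python analysis/04_deviance.py          --seed 1 --out results/run
python analysis/05_components.py        --seed 1 --out results/run
python analysis/06_associations.py      --seed 1 --out results/run
python analysis/07_brand_price.py       --seed 1 --out results/run
```

With seed 1 this prints (abridged):

```
wrote 201,196 first-dispensing claims for 19,146 patients
catalog: 60 drugs, 21 brand-only, 3 multi-class

21,638 post-washout person-years (9,503 persons), 3,193 observed bins
risk sets: 60 drugs, 40,055 training first-use events

fitted 60 drug models
holdout bias z: mean +0.25, SD 1.17, flagged |z|>3: 0

deviance matrix: 50 counties x 60 drugs
cell SD 0.045, per-drug mean in [-0.015, -0.006]

variance explained by top 4 components: 24.6%, 21.3%, 6.7%, 5.3%
leave-class-out stability: 79% of class x component dots above 0.95
CCA: 2 significant dimensions at p<0.01 (first correlation 0.98)

prescribing vs demographic distance: rho 0.69 (p 1.5e-171); vs geographic: rho 0.07 (p 9.2e-03)
border same-state coefficient -0.58 (SE 0.23, p 1.4e-02, 133 border pairs)
class recovery: observed ARI 0.049 vs null -0.001, separation p 9.5e-52

brand preference across 50 counties: SD 0.018, extremes [-0.037, +0.043]
demographics explain R^2 = 0.30 of brand preference
```

Reading the output: holdout z's near N(0,1) say the national model
predicts unseen persons without bias; per-drug deviance means near 0 say
counties deviate in both directions around the national expectation; the
two leading components (24.6% + 21.3% of variance, clearly separated from
the rest) recover the two planted latent prescribing axes; prescribing
distance tracks demographic distance (ρ = 0.69) and, weakly, geography;
bordering counties in the same state prescribe more alike (same-state
coefficient −0.58, reflecting the planted state-level offsets); drugs of a
therapeutic class cluster together by county profile far above the
permutation null (p ≈ 10⁻⁵¹); and the demographic model leaves most
brand-preference variation unexplained (the planted preference is
independent of demographics; the in-sample R² of 0.30 is what 12
predictors on 50 counties absorb by chance).

Equivalent one-call form:

```python
from rxvar import pipeline
out = pipeline.run_pipeline(pipeline.default_config(), "results/run", seed=1)
```

## Layout

```
src/rxvar/            the library: synthetic_claims, cohort, national_model,
                      deviance, components, association, brand_price, pipeline
analysis/             numbered narrative drivers over results/run
scripts/acceptance.py from-scratch recomputation of headline quantities
docs/methods.md       model, statistic, generator and design notes
tests/                unit + property + end-to-end acceptance tests
```
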