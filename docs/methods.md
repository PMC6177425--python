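# Methods

## The incidence model

The unit of analysis is the *person-year*. A prescription is *incident*
(first-time) if the drug never appears earlier in the person's observed
record; the first two calendar years of each person's observation are a
washout used only to establish prior non-use, and persons observed for two
or fewer years are dropped. Each post-washout person-year is assigned to a
bin

    b = (age band, calendar year, r, m)

with 5-year age bands, r the number of incident prescriptions (of any drug)
in that year, and m the number of years in the person's post-washout record
with at least one incident prescription (a static "consistency of care"
covariate). Sparse upper tails are pooled (defaults: r at 10+, m at 8+, age
at 85+; all caps are config keys).

Per drug d, the probability of first use in bin b is modelled as a
discrete-time survival logistic regression: a person-year is in the risk
set iff it has r > 0 and the person has never been observed on d before
(the year of first use counts in both numerator and denominator, the usual
discrete-time convention; persons whose first use of d fell in washout are
excluded from d's risk set outright). The design codes the four bin
variables as categorical dummies (first level as reference) with all six
pairwise interactions. The fit is L2-penalized, with the penalty expressed
per observation — so fitting grouped (n, y) bin counts is identical to
fitting exploded Bernoulli rows — and chosen from a grid by seeded
cross-validation on held-out binomial deviance. CV folds split each bin's
trials multinomially and its events by multivariate hypergeometric draws,
which is the grouped-data equivalent of randomly assigning person-years to
folds. A holdout set of persons (default 20%) never enters fitting and
supplies the unbiasedness check: per drug, predicted vs observed event
totals with a binomial z-score.

Choices the data did not dictate: ridge rather than lasso (many-level
dummies, no sparsity motive), 3 folds, the per-observation penalty grid
(1e-6 … 1e-3), and nearest-level snapping for bin levels unseen at fit time
(the factors are ordinal). All are config-exposed.

## The drug–county deviance

Per drug, national bin weights w_b = n_b / Σ_b' n_b' standardize every
county to the national bin distribution. The county's weighted at-risk
count, observed count, and model expectation are

    n_c = Σ_b w_b n_{b,c},  y_c = Σ_b w_b y_{b,c},  ŷ_c = Σ_b w_b n_{b,c} p̂_b

and the drug–county deviance is the signed root binomial deviance

    G = sign(y − ŷ) · [ y·log(y/ŷ) + (n−y)·log((n−y)/(n−ŷ)) ]^{1/2}

**The bracket carries no factor of 2.** The textbook deviance residual is
sign·√(2·[...]); this statistic is defined without the 2 and is implemented
exactly as defined, so under a clean binomial null G ≈ z/√2 and its SD is
about 0.71, not 1. Boundary conventions: x·log x → 0 limits at y = 0 and
y = n; ŷ is clamped to [ε, n − ε] with ε = 10⁻⁸·n; a bracket made slightly
negative by floating error near y ≈ ŷ is truncated to 0 before the root.
Counties below a weighted person-year floor (config; default 1.0) are
excluded. A companion log(y/ŷ) matrix uses the same conventions.

A scaling point worth knowing: because the weights multiply raw counts, the
weighted county totals scale like (county person-years) × Σ_b w_b², so |G|
grows with cohort size. At this package's default scale (20,000 patients)
null |G| per cell is small (~0.05–0.3); at tens of millions of person-years
the same statistic spans roughly ±3. Everything downstream standardizes the
drug columns and is therefore invariant to this scale.

## Latent components, CCA, association statistics

PCA is the SVD of the column-standardized (per-drug centered, unit
variance) counties × drugs matrix; components are oriented so the
largest-magnitude loading is positive, making signs reproducible.
Stability is assessed by refitting with one therapeutic class removed and
reporting |dot| between full and reduced loadings restricted to the shared
drugs (the full loading is renormalized over those drugs first).

CCA between the deviance block (drugs filtered to a usage quantile, default
top third — mirroring a most-used-drugs restriction) and the demographic
block (one of any pair with |r| > 0.95 dropped) is computed from the SVD of
the Cholesky-whitened cross-covariance. Significance per dimension uses
Wilks' lambda with Rao's F approximation; a permutation test (demographic
rows permuted, per-dimension largest-root statistic) is available because
the F approximation and the asymptotic spurious-correlation level both
degrade when counties are not many times the column count.

Association statistics: Euclidean county-pair distances on column-
standardized deviances, z-scored demographics, and raw lat/lon (planar, by
convention — haversine is an option); Spearman correlation with the
two-sided p from t = ρ√((n−2)/(1−ρ²)); OLS of bordering-pair deviance
distance on demographic distance plus a same-state indicator, restricted to
bordering pairs with at least one county on a state border, the same-state
p from the single-coefficient F-test. Class recovery: overlapping classes
are greedily merged by highest Jaccard overlap to a target count, drugs'
county profiles are hierarchically clustered (average linkage, Euclidean)
and cut to that many clusters, and the Adjusted Rand index is computed for
randomized single-class assignments (each multi-class drug assigned to one
of its classes at random) against a label-permutation null, with a
one-sided rank-sum separation p. Rank statistics use midranks; exact small-
sample p-values without ties, normal approximation with continuity
correction otherwise (scipy's policy). Elastic nets (including the
multi-task variant) use internally z-scored predictors so coefficients are
comparable, with CV-chosen penalties. Demographic imputation drops
variables with more than a threshold of missing counties (default 10) and
fills each remaining missing cell by OLS on the fully observed variables.

Brand preference is one joint OLS of deviance cells on therapeutic-class
membership columns plus a per-county (or per-state) × brand-only
interaction; class columns absorb class-level deviance so the interaction
coefficient reads as the county's excess use of brand drugs. If the brand
indicator happens to lie in the span of the class memberships the unit
coefficients are identified only up to a shared constant; the fit warns.
Class-level price correlations use a continuous brand-fraction column when
one is supplied; with the binary flag, ties cap the attainable pooled
Spearman correlation near 2√(3p(1−p)) ≈ 0.87 at p = 0.5.

## The synthetic claims world

No public claims data exists at this granularity, so the package generates
its own with known ground truth. Per person: a county, sex, birth year, and
a contiguous enrollment window of ≥ 3 years within 2003–2010. Per
person-year a utilization count u is drawn (negative binomial, mean 1.5,
size 1 — claims utilization is overdispersed); person-years with u = 0 have
no events. Each not-yet-used drug then first occurs with probability

    logistic( baseline_d + 0.25·(age−45)/10 + 0.05·(year−mid) + 0.6·log1p(u)
              + Σ_k L_{d,k} z_{c,k} + class_effect[class(d), c]
              + brand_pref_c · 1[d brand] + offset_{d,c} )

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| counties / states / drugs / classes | 50 / 8 / 60 / 12 | desk-scale analogue of ~2,300 counties x ~600 drugs |
| patients | 20,000 | all stages informative in minutes on one CPU |
| baseline logit range | (−5, −2.5) | ≈ 2 incident prescriptions per active person-year, as expected for a popular-drug catalog; much sparser utilization makes r nearly coincide with "had the event" and the model's conditioning on r then absorbs planted signals |
| latent components K | 2 | smallest K exercising subspace recovery |
| drug loading SD | 0.35 per component | county log-odds heterogeneity ~0.5 SD |
| class-county effect SD | 0.35 | within-class county profiles strongly correlated, as reported for e.g. thyroid hormones |
| state offset SD | 0.5 | state-level prescribing influences (laws, networks) |
| brand preference SD | 0.3 | moderate county-level price preference |
| demographic noise SD | 0.3 | demographics recoverable but not deterministic |

Sex is generated as a binary attribute and the default pipeline analyzes
the female cohort (the filter is a config key; `None` keeps everyone), so
one sex's utilization patterns do not confound the other's.

Structural choices: states are contiguous Voronoi cells around random
capitals; adjacency is the Delaunay triangulation of county coordinates
(polygon intersection is a data-access detail; real polygon-derived
adjacency can be supplied in the same two-column format); event weeks are
uniform within the year (downstream analysis is annual); enrollment is
contiguous (real claims have gaps; gap handling is not modelled). The state
offset perturbs prescribing only — demographics derive from the pre-offset
latent scores — because the border regression specifically isolates state
effects *beyond* demographic similarity; a state effect mediated by
demographics could not drive it. Every planted quantity (loadings, latent
scores, class effects, brand preferences, offsets) is saved in truth.json
next to the data.

What passing tests on this world do and do not show: they validate the
estimators — calibration under the null, recovery of planted structure at
realistic signal-to-noise — not any substantive claim about US prescribing.
Real claims features deliberately absent: non-uniform regional sampling,
enrollment gaps, diagnosis codes, plan structure, dosage and refills, and
drug entry/exit over time.

## The planted-offset power experiment

The end-to-end detectability check doubles the first-use odds of the 10
most common drugs, each in its own disjoint set of 3 counties, with all
other county heterogeneity off, and asks how often the planted cells'
deviance is positive. Two design points matter. Offsets go on common drugs
because a drug with ~1 expected county event cannot support a sign test at
this scale (the analysis focuses on highly prescribed drugs throughout).
County sets are disjoint because stacking many doubled drugs in one county
shifts that county's whole r/m bin distribution, and a model that
conditions on utilization then absorbs part of the planted signal — a real
property of utilization-conditioned incidence models, visible here as the
observed/expected ratio rising from 1.43 (stacked) to 1.64 (disjoint)
against a clean-data value of 2.

## Problem sizes and runtime

The canonical runs use 50 counties × 60 drugs × 20,000 patients (≈ 5
minutes per pipeline run on one CPU, dominated by the per-drug CV fits);
null calibrations use 10,000 replicates per test; module tests run on a
4,000-patient world. These sizes were chosen so every stage has enough
events to be statistically meaningful while a full validation pass stays
comfortably interactive.

## Known limitations

* The deviance magnitude depends on cohort scale (see above); compare G
  values only within a run, or standardize columns.
* m is computed over the person's full post-washout record (static); a
  time-varying alternative (years with events up to the current year) is a
  plausible reading of the same definition and is switchable in principle
  but not the default.
* With 50 counties the CCA is close to its sample-size floor even after
  filtering; the permutation test is the trustworthy significance path
  there.
* The class-collapse procedure (greedy highest-Jaccard merging) is one
  reasonable choice among several; the target count is config.
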