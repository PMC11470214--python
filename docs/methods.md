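# Methods

`vioscales` implements a two-stage analysis of functional-impairment scales
in individuals exposed to violence, of the kind collected in a forensic
medicine consultation registry. Stage one builds a *typology of violence
situations* from the circumstances of each consultation; stage two evaluates
nine 7-level Likert scales against that typology: descriptive medians,
between-physician comparisons, regressions on days of total incapacity to
work (TIW), and profile-matched inter-/intra-rater concordance. Because
registries of this kind are private, the package ships a synthetic-cohort
generator that reproduces the statistical structure every stage assumes, so
the whole pipeline is testable end to end against a known ground truth.

## The synthetic cohort

Each of `n` patients carries a latent violence-situation profile drawn from
a five-profile mixture (default mixing weights 779 : 749 : 719 : 1092 : 841,
the relative sizes of the five situation types the analysis is designed to
recover: low-impact assaults, multiple-assailant battery, police violence in
custody, high-impact single-assailant assaults, and repeated intimate-partner
violence). Conditional on the profile:

* **Binary circumstance features** (44 variables over patient, assault type,
  physical trauma, assailant, location and assault-characteristic blocks)
  are independent Bernoulli draws with profile-specific frequencies
  (`data/default_config.yaml`). Independence is deliberate: only marginal
  frequencies are specified, and inventing a dependence structure would add
  unverifiable assumptions.
* **Age and consultation delay** are log-normal, parameterized by median
  and quartiles per profile; ages are resampled below 10 years (the
  eligibility floor).
* **Scale scores** follow an additive latent-continuum model,
  `score = clamp(round(mu[profile, scale] + b[physician] + s[patient] + e), 0, 6)`,
  with a per-physician bias `b ~ N(0, 0.3²)` constant across that
  physician's patients, a per-patient severity `s ~ N(0, 1.3²)` shared
  across the nine scales, and observation noise `e ~ N(0, 0.9²)`.
  Rounding+clamping a latent Gaussian is the simplest mechanism that yields
  skewed ordinal distributions with heavy ties at the 0 and 6 boundaries.
  The physician bias is exactly the systematic interrater-disagreement
  component the concordance stage is designed to detect; the defaults were
  fixed once by a pilot run so that pooled interrater W falls in the mild-
  to-good band (about 0.49–0.64) typical of real-life rating conditions.
* **TIW** is `max(0, round(0.5 + 0.45·pain_assault + 0.1·fear_assault +
  0.9·functional_impairment + N(0, 1.5²)))` days. The coefficient set was
  chosen once so that per-profile TIW medians land near 3/4/2/4/4 days;
  univariate regression betas on the generated data are *marginal* effects
  and therefore exceed these joint coefficients wherever scales correlate
  through the profile and severity structure.
* **Missingness** is applied completely at random at the record level: a
  record is affected with probability `missing_rate` (default 0.1931) and
  loses a random nonempty subset of its scale scores. MCAR matches the
  assumption that complete and incomplete records are comparable.
* **Certificates** are rendered from a fixed French sentence template; each
  true symptom flag embeds one lexicon term, mutated by one random character
  edit with probability `typo_rate` (default 0.1). Terms of ≥5 characters
  are preferred for embedding so that a single typo stays inside the
  matcher's tolerance band. Ten physicians with uniform caseloads are the
  default (45 physician pairs).

What the generator does **not** emulate: temporal evolution or repeat
consultations, dependence among circumstance features beyond the profile,
informative missingness, physician-by-profile interactions, and free-text
phenomena beyond single-character typos (negation, abbreviations, section
structure). Passing tests therefore demonstrate that the *procedures* are
correct and calibrated under the stated model, not that real certificates
or real rating behaviour satisfy that model.

## Certificate mining

Text is normalized (lower-case, accents stripped, punctuation collapsed —
an idempotent map), tokenized, and matched against a concept lexicon under
a length-banded Levenshtein tolerance: 0 edits for terms shorter than 5
characters, 1 for 5–8, 2 beyond 8. The bands prevent short-word false
positives (`pour` must not fire `peur`) while absorbing realistic typos in
longer terms. Multi-word terms are matched against token n-grams of the
same width. Negation is not handled; extraction is a pure function of
(text, lexicon). The shipped French lexicon covers sleep disorders, loss of
appetite, stress symptoms, pain and fear, and is user-replaceable JSON.

## Typology

**Dissimilarity.** Gower's coefficient over the circumstance variables:
0/1 mismatch for binary variables, range-scaled absolute difference for
numeric ones, pairwise-present renormalization for missing entries. Scales,
symptom flags and TIW are excluded from the clustering by default — the
scales are evaluated *against* the profiles, so letting them define the
profiles would be circular. TIW can be included via the feature spec.

**Clustering.** Classical PAM: BUILD seeds k medoids greedily by maximal
cost reduction; SWAP repeatedly applies the best-improvement
medoid/non-medoid exchange. Two numerical choices matter. All ties break
toward the lowest index, making every run deterministic given the input
order (resampling reproducibility then needs no randomness inside the
clusterer). And SWAP additionally may take a bounded number (2k) of
cost-*neutral* exchanges, cycle-protected and scanned in lowest-index
order: dissimilarities built from many binary variables are heavily tied,
producing cost plateaus on which strict descent can stall one step away
from a better basin. With this extension PAM matches exhaustive medoid
search on random small instances except the ~3% that are strict single-swap
local optima — a property of the classical algorithm itself (R's
`cluster::pam` returns the same suboptimal cost on such instances).

**Consensus scan.** The cohort is subsampled without replacement
`n_resamples` times (default 50; fraction 0.8 at desk scale, 0.2 for
study-scale cohorts) and each subsample is clustered with PAM at every
candidate k (default 2–10). Sharing the subsample draws across k — the
canonical formulation of the consensus framework — keeps pure sampling
noise out of the between-k comparison. The consensus matrix holds the fraction of co-subsampled runs in
which each pair co-clustered; pairs never drawn together are flagged
undefined and excluded from the metrics (the silhouette, which needs a
complete matrix, imputes them with the mean defined off-diagonal entry).
Four metrics summarize each k: PAC (share of defined entries in the
ambiguity band (0.1, 0.9); lower is stabler), mean within-cluster consensus
under the reference full-data PAM partition at that k, mean Jaccard overlap
between each run's co-membership pairs and the reference partition
restricted to the subsample, and the silhouette of the reference partition
on 1−consensus. The selected k is the best mean rank across the four
metrics, ties to the smaller k.

A caveat discovered during development and worth keeping in mind: the
stability metrics *saturate* when clusters are near-deterministic and
subsamples overlap heavily — merging two well-separated profiles is then
perfectly stable, and k below the truth is indistinguishable from the
truth. Discrimination comes from subsample diversity, i.e. small subsample
fractions, which is why the study-scale scan uses 20% subsamples.

## Concordance

Scales cannot be re-administered (a first consultation for violence is not
repeatable), so agreement is measured on *matched* patients. For a
physician pair, patients are matched within each shared profile by a
uniform-random bijection between equal-size subsamples of the two
physicians' patient sets; for a single physician, by a uniform-random
partition of their patients into disjoint pairs (one dropped if odd). The
paired scores form an n×2 ratings matrix and agreement is the tie-corrected
Kendall coefficient of concordance

    W = 12 S / (m²(n³ − n) − m ΣTⱼ),   S = Σᵢ (Rᵢ − m(n+1)/2)²,

with mid-ranks per rater column and tie term `Tⱼ = Σ(t³ − t)`. For m = 2
without ties, `W = (ρ_Spearman + 1)/2`, which serves as an independent
cross-check. A vanishing denominator (e.g. a constant rater column) is an
undefined result and is reported as such, never as a number. W is computed
per profile and pooled (pairs concatenated across profiles); both are
emitted because they answer different questions — pooled W credits
between-profile discrimination, per-profile W only within-profile
agreement. Because one random matching is a lottery, the matching is
redrawn R times (default 100) and W is summarized by its mean and 2.5/97.5
percentiles.

The fine-profile sensitivity analysis re-clusters at a much larger k
(default n/5, at most n/2) and repeats the concordance analysis with the
same matching seeds, so any change in W is attributable to profiling
granularity alone. If coarse profiles hid systematic within-profile
differences, finer profiles should raise W.

## Scale statistics

Descriptives are median (Q1–Q3, linear interpolation). Between-physician
comparisons use the tie-corrected Kruskal-Wallis H with the chi-square
approximation, followed by Conover-Iman pairwise tests computed on the same
pooled ranking,

    t = (R̄ᵢ − R̄ⱼ) / sqrt(S² · (N−1−H)/(N−k) · (1/nᵢ + 1/nⱼ)),

with Student-t reference on N−k degrees of freedom and Bonferroni
adjustment over all physician pairs (α = 0.05). The tie-corrected H enters
the (N−1−H) factor; `N−1−H ≤ 0` is reported as undefined. Comparisons are
run overall and stratified within profiles — the contrast between the two
exposes how much apparent between-physician disagreement is mere case-mix
confounding. TIW regressions are univariate OLS with normal-theory 95% CIs,
complete cases per scale.

## Eligibility and orchestration

The eligibility filter removes, in order: age below 10; unintentional
violence or neglect; consultations more than 30 days (720 h, boundary
retained) after the incident; patients of physicians with fewer than 300
patients in the loaded cohort (one study year assumed); second evaluations;
and incomplete records (scales + TIW, plus clustering features by default).
Each excluded record is logged under the first rule it trips, so the log
sums exactly to input minus output.

`run_pipeline` derives one sub-seed per stage from a single master seed via
named `SeedSequence` children; two runs with the same master seed produce
byte-identical artifacts, and the report manifest records the seeds and
SHA-256 digests of every output.

## Problem sizes used in the test suite

The suite exercises the study-scale path once (n=4180, 50 resamples of 20%,
k=2–10, about 5 minutes) and otherwise uses cohorts of 200–1500 with
proportionally reduced resampling, which the pilot runs showed to be the
smallest sizes at which the statistical assertions (3σ calibration bands,
planted-parameter recovery, type-I error in [0.035, 0.065]) are stable.

## Known limitations

* PAM is a local search; optimality is guaranteed nowhere, only observed on
  small instances (see above).
* The mean-rank selection rule weights the four stability metrics equally;
  with very few candidate k or saturated metrics it degrades to "smallest
  k" (with a logged warning).
* The concordance design measures agreement between *different patients
  judged similar*, not repeated ratings of the same patient; residual
  within-profile specificities deflate W, which is precisely what the
  fine-profile sensitivity quantifies.
* Binary features are treated symmetrically in the Gower coefficient
  (0/0 counts as agreement), which is the standard choice for circumstance
  indicators but differs from Gower's asymmetric treatment of rare traits.
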