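# vioscales

Typology of violence situations and reproducibility analysis of
functional-impairment scales in forensic medicine.

## The problem

Forensic physicians examine individuals exposed to violence and certify the
outcome for the courts — in France as days of *total incapacity to work*
(TIW). Part of that assessment is irreducibly subjective: pain, fear, and
the perception of a life threat, reported by the patient and rated on
7-level (0–6) Likert scales alongside physician-rated functional
impairment, interaction quality, and a psychosomatic index. Two questions
decide whether such scales are usable as evidence: do they contribute to
the overall measurement of functional impairment, and do different
physicians score them consistently? The second question cannot be answered
with a classic test-retest design — a first consultation for violence
cannot be repeated — so consistency must be assessed on *different patients
who experienced similar situations of violence*.

`vioscales` implements that workflow as a reusable, tested pipeline:

1. **Typology** — patients are clustered on the circumstances of the
   assault (demographics, assault type, physical trauma, assailant,
   location, assault characteristics) with Partitioning Around Medoids
   (PAM) on Gower dissimilarities; the number of profiles is chosen by a
   consensus-resampling scan combining four stability metrics (PAC, mean
   within-cluster consensus, Jaccard stability, consensus silhouette) by
   mean rank.
2. **Scale characterization** — medians/IQR per profile, Kruskal-Wallis and
   Bonferroni-adjusted Conover-Iman comparisons of ratings across
   physicians (overall and within profiles), and univariate OLS regressions
   of TIW on each scale.
3. **Concordance** — patients matched at random within profiles, per
   physician pair (interrater) and per physician (intrarater); agreement is
   the tie-corrected Kendall coefficient of concordance
   `W = 12S / (m²(n³−n) − mΣTⱼ)`, with repeated matching (default R=100)
   and percentile summaries, plus a fine-profile sensitivity rerun.
4. **Synthetic cohorts** — since real registries are private, a first-class
   generator produces cohorts with the assumed structure: five latent
   violence-situation profiles, profile-conditional features, ordinal
   scales with physician bias / patient severity / observation noise, a
   linear scale→TIW link, record-level missingness, and typo-bearing French
   certificate text mined back by a fuzzy lexicon matcher.

See `docs/methods.md` for the model and every numerical choice.

## Worked example

```python
import vioscales as v

# a small synthetic registry: 2 physicians, no missing scores
cfg = v.default_config(n_patients=700, n_physicians=2, seed=3, missing_rate=0.0)
cohort = v.generate_cohort(cfg)

# typology: Gower + consensus-resampled PAM over k = 2..8
dissim = v.gower_dissimilarity(cohort)
scan = v.consensus_clustering(dissim, k_range=range(2, 9),
                              n_resamples=30, subsample_frac=0.4, seed=0)
print("selected number of profiles:", scan.selected_k)

clustering, summary = v.assign_profiles(cohort, dissim, scan.selected_k)
labels = v.labels_series(clustering)

# association of pain (during the assault) with days of incapacity
reg = v.ols_univariate(cohort, "pain_assault")
print(f"beta = {reg.beta:.2f} days/point (95% CI {reg.ci_low:.2f} to {reg.ci_high:.2f})")

# interrater agreement on that scale, matched within profiles
res = v.concordance_analysis(cohort, labels, "pain_assault",
                             contexts=[(0, 1)], repetitions=50, seed=0)
r = res[(0, 1)]
print(f"pooled Kendall W = {r.W_mean:.2f} [{r.W_p2_5:.2f}, {r.W_p97_5:.2f}]")
```

Output:

```
selected number of profiles: 4
beta = 0.95 days/point (95% CI 0.86 to 1.03)
pooled Kendall W = 0.54 [0.48, 0.57]
```

At this desk scale (700 patients, realistic feature noise) the stability
scan merges the two closest of the five generating profiles and selects 4;
at study scale (n=4180, 50 subsamples of 20%) the same scan recovers all
5 — that run is what `scripts/acceptance.py` reproduces. The regression
slope is the *marginal* association of the pain scale with TIW (larger
than the planted direct coefficient, because scales correlate through the
profile and severity structure), and pooled interrater W ≈ 0.54 is the
mild agreement produced by the generator's default rater-effect
magnitudes.

The same stages are available from the shell:

```sh
vioscales simulate --n 700 --seed 3 --out cohort.csv
vioscales cluster --input cohort.csv --out typology/
vioscales concordance --input cohort.csv --labels typology/labels.csv --out W.csv
vioscales all --seed 3 --out report/        # full pipeline + manifest
```

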