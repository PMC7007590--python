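# digiphen

Digital phenotyping of adolescent depression from smartphone data.

Clinically depressed adolescents are typically assessed with in-clinic
psychometric instruments — PHQ-9, HAM-D, HAM-A — administered every few
weeks, leaving the day-to-day course of their symptoms invisible.
Passively logged smartphone streams (GPS, step counter, call and SMS
metadata, ambient light, screen state) together with brief daily 0–100
mood/anxiety sliders from the teen and from a parent acting as a human
observer offer a continuous, low-burden alternative.  `digiphen`
implements the full analysis pipeline for such a study, for researchers
in mobile mental-health sensing:

1. **Feature extraction** from raw streams, per subject-day:
   - *Mobility*: day/night step counts; total geodesic distance
     (Vincenty's inverse formula on WGS84); transition time by mode
     (automobile 7–45 m/s, walking 1–2 m/s, otherwise unknown);
     **location variance** `ln(var(lat) + var(lon))` over the day's
     stationary fixes (speed < 0.2 m/s); number of frequently visited
     places, found by growing K-means until every stationary fix lies
     within 500 m of a cluster centre; **normalized entropy**
     `−Σᵢ pᵢ ln pᵢ / ln N`, where `pᵢ` is the fraction of the day's
     dwell time at place *i* and *N* is the study-wide place count; and
     home-stay fraction.
   - *Social*: daily call/SMS counts, durations and lengths restricted
     to the study-wide top-10 most frequent contacts (MD5-hashed —
     raw identifiers never touch disk).
   - *Context*: night hours darker than τ_I (a sleep proxy) and hours
     with screen-on fraction above τ_S.
2. **Correlation**: daily features averaged over the 14 days before
   each biweekly clinic visit, then pooled Pearson correlations against
   PHQ-9 / HAM-D / HAM-A with significance stars (* p<.1, ** p<.05,
   *** p<.01).
3. **Prediction**: PHQ-9 regression over nine preset feature subsets
   with a linear model and a degree-3 polynomial-kernel SVR, 4:1
   train/test split, reporting test RMSE, the variance score
   (test-set R², possibly negative) and the accuracy conversion
   `100 × (27 − RMSE)/27`.
4. **Synthetic cohort**: clinical sensor datasets of this kind are not
   publicly deposited, so the package ships a generator that plants a
   latent daily severity trajectory per teen (bounded random walk,
   start ~ N(12.72, 5.97) on the PHQ-9 scale) and drives every stream
   from it with sign-constrained effect sizes — fewer steps, fewer and
   closer places, more uniform dwell, shorter calls, fewer texts, lower
   reported mood at higher severity, with light and screen as planted
   null channels.  Every downstream claim is tested against this known
   ground truth.

## Worked example

```bash
digiphen run-all --seed 7 --out demo/
cat demo/summary.txt
```

which prints (20-family synthetic cohort, 8 weeks):

```
biweekly observations: 80
teen compliance: 78.7% (881/1120 days)
parent compliance: 94.6% (1060/1120 days)

strongest correlations with PHQ-9:
  teen_mood                    r=-0.98 ***
  teen_anxiety                 r=-0.98 ***
  home_stay                    r=-0.98 ***
  parent_mood                  r=-0.97 ***
  n_sms_all                    r=-0.97 ***
  n_sms_top10                  r=-0.97 ***
  parent_anxiety               r=-0.97 ***
  normalized_entropy           r=+0.93 ***

best prediction: teens_parents_inputs / linear RMSE=1.17 accuracy=96% (25.83/27)
```

Reading this: each of the 20 teens contributes 4 biweekly visits
(80 observations).  Compliance is the fraction of enrolled days with a
submitted daily report.  The correlation block shows that lower
self-reported mood, more home-staying, fewer text messages and more
uniform dwell across places all track higher PHQ-9 — the directions the
generator planted.  The last line is the best cell of the 9-subset × 2
-model prediction grid (`demo/predictions_wide.csv`): an RMSE of 1.17
PHQ-9 points equals 96% accuracy on the 0–27 range.  Correlations and
errors on synthetic cohorts are cleaner than on real clinical data;
their magnitudes depend on the planted effect and noise scales, so the
package's tests assert directions and recovery, not magnitudes.

The same stages are available piecemeal (`digiphen simulate`,
`extract-mobility`, `extract-social`, `extract-context`, `merge`,
`correlate`, `predict`), all exchanging plain CSV, and as a library:

```python
from digiphen import CohortConfig, simulate_cohort, extract_mobility
bundles, truth = simulate_cohort(CohortConfig(n_families=5, seed=0))
mobility = extract_mobility(bundles[0])   # one row per subject-day
```

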