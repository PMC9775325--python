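# sentinelgaze

Analysis of visual-monitoring behaviour in sentinel birds from quadrant-coded
head-movement event logs.

Sentinels scan from a vantage point by turning the head and holding a *look*
in one of four 90° quadrants around the body axis (quadrant 1 faces forward;
mid-point angles 0°, 90°, 180°, 270°, positive angles to the animal's right).
From a timestamped stream of alternating head moves and looks, this package:

- derives **look durations** (the still interval, excluding the preceding
  head move), **head-move durations**, and **return times** — how long the
  gaze takes to re-enter a reference quadrant after an excursion of one or
  more looks elsewhere;
- fits the four candidate look-duration distributions — normal, log-normal,
  negative exponential, Weibull — as Bayesian hierarchical regressions

  `η = β₀ + β_gs·G + β_status + u_group + v_individual`

  (identity link for the normal family, log link otherwise) and ranks them by
  PSIS-LOO expected log pointwise predictive density (ELPD), treating
  differences ≤ 4 as similar predictive performance;
- tests distributional adequacy per focal observation with a **Monte-Carlo
  Kolmogorov–Smirnov** test: B = 1000 synthetic samples from the fitted
  distribution, re-fitted before each KS statistic (a parametric bootstrap /
  Lilliefors-style correction), `p = (1+#{D_b ≥ D_obs})/(B+1)`, adequate when
  p > 0.05;
- summarises head orientation per observation by the **duration-weighted mean
  angle**, attaches a parametric-bootstrap 95% CI under a fitted von Mises
  distribution, declares a left/right **side bias** when 0° falls outside the
  CI, and reports exact (Clopper–Pearson) binomial CIs on the proportion of
  right- vs left-biased individuals per status class;
- ships a **synthetic sentinel-bout generator** (first-order Markov quadrant
  chain with configurable stationary occupancy and persistence, hierarchical
  log-normal durations, frame-quantised head moves, optional injected
  orientation bias) so the entire pipeline is testable without field
  recordings.

## Worked example

```python
import numpy as np
from sentinelgaze import (SimConfig, simulate_population, derive_looks,
                          extract_return_times, fit_hier_model, compare_elpd,
                          SamplerConfig, mc_ks_test, summarize_orientation)

events, meta, truth = simulate_population(SimConfig(n_observations=30, seed=11))
looks = [lk for m in meta for lk in derive_looks(events[m.obs_id])]
print(len(looks))                                   # 4274
d = [lk.duration for lk in looks]
print(round(float(np.median(d)), 2))                # 0.94  (pooled median, s)

fits = {f: fit_hier_model(looks, meta, f, SamplerConfig(seed=s))
        for f, s in [("lognormal", 1), ("exponential", 2), ("normal", 3)]}
print(compare_elpd(fits).table[["family", "elpd_diff", "similar"]])
#         family    elpd_diff  similar
# 0    lognormal     0.000000     True
# 1  exponential   415.845452    False
# 2       normal  2317.541669    False

r = mc_ks_test(d[:200], "lognormal", B=1000, seed=4)
print(round(r.p_mc, 3), r.fit_ok)                   # 0.257 True

s = summarize_orientation(looks[:150], B=2000, seed=5)
print(round(s.mean_angle, 1), s.bias)               # -16.5 none
```

The ELPD table reads: the log-normal model predicts unseen looks best; the
exponential and normal families fall hundreds of ELPD units behind (well past
the similarity threshold of 4), so look durations are humped and
right-skewed, not memoryless and not symmetric. The KS p-value (0.257 > 0.05)
says the log-normal is an adequate per-observation description; the
orientation summary finds no side bias in this (unbiased) simulation.

The same pipeline runs from the shell:

```bash
sentinelgaze simulate --seed 7 --out-dir study
sentinelgaze derive --input study/event_log.csv --out-dir study
sentinelgaze fit --input study/event_log.csv --family all --seed 1 --out-dir study
sentinelgaze gof --input study/event_log.csv --B 1000 --seed 2
sentinelgaze orient --input study/event_log.csv --seed 3 --out-dir study
sentinelgaze run --seed 4 --out-dir results   # everything, plus a manifest
```

Event logs are plain CSV (one row per head move or look:
`obs_id, group_id, individual_id, status, group_size, kind, t_start, t_end,
quadrant`); see `docs/methods.md` for the model and generator details.

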