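"""Pilot-trial metrics: feasibility rates, paired changes, HRQoL, fitness.

Computes the feasibility rates of the bundled recruitment-flow fixture,
a complete-case paired contrast on simulated fitness percentiles, HRQoL
dichotomization/indexing on toy profiles, and a 6-minute-walk-test
percentile lookup against a small synthetic normative table.
"""

import numpy as np
import pandas as pd

from actibout import (
    FitnessRecord,
    HRQoLRecord,
    ScoreSet,
    dichotomize_hrqol,
    feasibility_rates,
    flow_fixture,
    index_hrqol,
    paired_change,
    sixmwt_percentile,
    summarize_scores,
)

print("feasibility rates from the recruitment flow:")
for name, r in feasibility_rates(flow_fixture()).items():
    print(f"  {name:<20} {r.percent:>3}%  ({r.numerator}/{r.denominator})")

scores = ScoreSet("tracker_enjoyment", [20, 40, 40, 60, 60, 75, 90, 92.5, 95, 100])
s = summarize_scores(scores)
print(f"\nacceptability item {s.item!r}: median {s.median:.0f} "
      f"(IQR {s.q1:.1f}-{s.q3:.1f}), n={s.n}")

rng = np.random.default_rng(1)
pre = np.clip(rng.normal(44, 32, size=16), 1, 99)
post = np.clip(pre + rng.normal(17, 30, size=16), 1, 99)
r = paired_change(pre, post)
print(f"\npaired fitness-percentile change (n={r.n}): "
      f"{r.mean_change:+.1f} (95% CI {r.ci_low:.1f} to {r.ci_high:.1f}, p={r.p:.3f})")

profile = HRQoLRecord((1, 2, 1, 3, 1), vas=80)
flags = dichotomize_hrqol(profile)
toy_value_set = {(1, 1, 1, 1, 1): 1.0, (1, 2, 1, 3, 1): 0.82}
print(f"\nHRQoL profile {profile.levels}: any-problem dimensions = "
      f"{[d for d, f in flags.items() if f]}")
print(f"index value under the toy value set: {index_hrqol(profile, toy_value_set)}")

# synthetic normative table (not real reference values)
norms = pd.DataFrame(
    [{"sex": "F", "age": 10, "quantile": q, "distance_m": d}
     for q, d in ((10, 420), (25, 460), (50, 500), (75, 540), (90, 580))]
)
rec = FitnessRecord(distance_m=530.0, age=10, sex="F")
print(f"\n6MWT {rec.distance_m:.0f} m (age {rec.age}, sex {rec.sex}) -> "
      f"{sixmwt_percentile(rec, norms):.0f}th percentile of the synthetic norms")
print("\nRates are report-style integer percents; the paired change is the")
print("complete-case mean post-minus-pre difference with a t-based interval.")
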