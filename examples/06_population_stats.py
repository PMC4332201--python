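"""Population statistics: CV, correlation, time-course and power-law fit.

These are the summary statistics the per-cell tables feed into:
cell-to-cell coefficient of variation, marker-vs-FBA Pearson correlation,
experiment-level time-course means ± SEM with Student's t-tests, and the
power-law trend fit y = a·x^b.
"""

import math

import numpy as np
import pandas as pd

import hepcyto as hc

rng = np.random.default_rng(0)

# CV: lognormal heterogeneity recovered against the closed form
sigma = math.sqrt(math.log(1 + 0.15**2))
sample = rng.lognormal(math.log(500) - sigma**2 / 2, sigma, 1000)
cv = hc.coefficient_of_variation(sample)
print(f"CV of 1000 cells: {cv:.1f}% (closed form for this lognormal: 15.0%)")

# correlation: independent marker/FBA pairs stay inside the null band
r, n = hc.correlate_per_cell(rng.standard_normal(1150),
                             rng.standard_normal(1150))
print(f"Pearson r of independent pairs: {r:+.3f} at n={n} "
      f"(95% null band is ±{2 / math.sqrt(n):.3f})")

# time-course: three experiments per condition and time point
rows = [
    {"condition": cond, "time_h": t, "experiment": e,
     "value": level * decay * (1 + rng.normal(0, 0.05))}
    for cond, level in (("2D", 500.0), ("3D", 520.0))
    for t, decay in ((7.0, 1.0), (32.0, 0.2 if cond == "2D" else 0.6))
    for e in range(3)
]
summary, comps = hc.summarize_timecourse(pd.DataFrame(rows),
                                         fold_between=[(7.0, 32.0)])
print("\ncondition means ± SEM (n = 3 experiments):")
print(summary.to_string(index=False))
print("7h/32h fold-changes:",
      summary.attrs["fold_changes"].fold_change.round(2).tolist())
print("t-test 2D vs 3D at 32 h: p =",
      float(comps.query("time_h == 32.0").p_value.iloc[0]).__round__(4))

# power law: the nuclear-size / Hoechst trend model
x = np.array([7.0, 16.0, 32.0, 72.0, 168.0])   # hours in culture
y = 12.0 * x**0.12                              # nuclear diameter, µm
fit = hc.fit_power_law(x, y)
print(f"\npower-law fit y = a*x^b: a={fit.a:.2f}, b={fit.b:.3f} "
      "(exact recovery on noiseless data)")
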