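"""Estimate LT50 from a freeze-response series.

Builds specific extracellular resistance observations at eight freezing
temperatures (three replicates, 2% noise) from a logistic with a known
inflection at -45 degC, fits the four-parameter sigmoid and prints the
estimated semi-lethal temperature.
"""

import numpy as np

import frosteis as fe

TRUE = (40.0, -0.3, -45.0, 5.0)  # (A, B, C, D); C is the planted LT50
temps = np.arange(-10.0, -81.0, -10.0)
clean = np.asarray(fe.sigmoid(temps, TRUE))

rng = np.random.default_rng(7)
t_all, y_all, reps = [], [], []
for rep in (1, 2, 3):
    t_all.append(temps)
    y_all.append(clean * (1 + rng.normal(0, 0.02, len(temps))))
    reps.append(np.full(len(temps), rep))

series = fe.FreezeResponseSeries(
    condition=("Pi", 100.0, "Slow", 0.5),
    temperatures_c=np.concatenate(t_all),
    re_specific=np.concatenate(y_all),
    replicates=np.concatenate(reps),
)

est = fe.estimate_lt50(series)
print(f"estimated LT50 = {est.lt50_c:.2f} degC  (planted: -45.00)")
print(f"r^2 = {est.r_squared:.4f}   converged = {est.converged}")
print(f"flags: {sorted(est.quality_flags) or 'none'}")
# The LT50 is the inflection of r_e(T): the temperature at which half of
# the full resistance transition - half-lethal membrane injury - occurred.
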