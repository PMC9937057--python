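"""Fit the exponential learning model and recover its two features.

One learner's geometric-entropy series I(t) = a + c*exp(-b*t) + noise is
fitted by profiled least squares; the prediction stage uses the pair
(a, e = c*exp(-b)): the performance plateau and the curve's elevation
above it after the first trial.
"""

import numpy as np

import climblearn as cl
from climblearn.curves import MetricSeries

rng = np.random.default_rng(3)
t = np.arange(84, dtype=float)
a_true, b_true, c_true = -0.4, 0.07, 1.3
values = a_true + c_true * np.exp(-b_true * t) + rng.normal(0, 0.15, size=84)
values[rng.random(84) < 0.05] = np.nan  # a few equipment voids

fit = cl.fit_exponential(MetricSeries("demo", "GE", t, values))
a_hat, e_hat = cl.extract_features(fit)
e_true = c_true * np.exp(-b_true)

print(f"observed points: {fit.n_points}/84 (voids are dropped, not imputed)")
print(f"a  (plateau):          true {a_true:+.3f}   fitted {a_hat:+.3f}")
print(f"e  (learning feature): true {e_true:+.3f}   fitted {e_hat:+.3f}")
print(f"fit MSE: {fit.mse:.4f} (noise variance was {0.15**2:.4f})")
print("\nThe pair (a, e) summarizes where the learner ends up and how much")
print("learning the curve contains; b and c separately are far less stable.")
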