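"""Trend fitting over a developmental series.

Simulates a series of normalized stationary entropies decaying over days
post-conception, then fits both trend models: an ordinary least-squares line
(whose extrapolation eventually predicts impossible negative entropy) and the
bounded exponential exp(a*t) + b whose asymptote b is the residual disorder.
"""

import numpy as np

from sementropy.trend import StagePoint, StageSeries, fit_exponential, fit_linear

rng = np.random.default_rng(0)
t = np.arange(4.0, 18.0)  # days post-conception
y = np.exp(-0.2 * t) + 0.6 + rng.normal(0, 0.02, t.size)  # noisy series

series = StageSeries(points=[
    StagePoint(model_id=f"model{i:02d}", stage=f"TS{i + 9}", t=ti,
               e0_norm=None, epi_norm=float(yi))
    for i, (ti, yi) in enumerate(zip(t, y))
])

lin = fit_linear(series, which="epi")
exp = fit_exponential(series, which="epi")
print(f"linear fit:      slope {lin.params[0]:+.4f}/day, "
      f"intercept {lin.params[1]:.4f}, mse {lin.mse:.2e}")
print(f"exponential fit: rate {exp.params[0]:+.4f}/day, "
      f"offset {exp.params[1]:.4f}, mse {exp.mse:.2e}")
print(f"linear fit predicts entropy 0 at day {-lin.params[1] / lin.params[0]:.1f}"
      " -- beyond that it turns negative, which is uninterpretable;")
print(f"the exponential instead levels off at {exp.params[1]:.3f}.")
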