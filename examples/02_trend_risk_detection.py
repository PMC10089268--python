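"""Detect an unhealthy behavioural trend in a daily step series.

Simulates 12 weeks of steps for one child with a known decline starting at
day 40, runs the risk detector (decompose -> piecewise slopes -> classify ->
reference point -> forecast) and prints what it found.
"""

import datetime as dt

import numpy as np

import habitcoach as hc
from habitcoach.simulate import VariableSim

start = dt.date(2026, 1, 5)
spec = VariableSim(mean=8000, between_child_sd=0, daily_noise_sd=800,
                   seasonal_amplitude=600)
rng = np.random.default_rng(4)
ts, truth = hc.simulate_child_series(
    rng, "leo", "steps", spec, n_days=84, start_date=start,
    changepoints=[(40, -150.0)], artifact_rate=0.02,
)

cfg = hc.DetectorConfig(min_slope=100, max_slope=2000,
                        harm_direction="descending_is_harmful", horizon=7)
res = hc.detect_risk(ts, cfg)

print(f"injected changepoint : day 40 ({start + dt.timedelta(days=40)})")
print(f"verdict              : {res.verdict.value}")
print(f"reference point      : {res.reference_point}")
print(f"segment slopes       : {[round(s.slope, 1) for s in res.segments]} steps/day")
print(f"classes              : {[c.value for c in res.classes]}")
print(f"screened artifacts   : {len(res.artifacts)} day(s)")
if res.forecast:
    print(f"7-day forecast       : {[round(v) for v in res.forecast]}")
# The reference point is the estimated day the decline began; the verdict is
# 'confirmed by forecast' because extrapolating the final segment continues
# the decline. Single-day dropouts are screened as device artifacts.
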