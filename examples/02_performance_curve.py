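"""Fit and interrogate the zero-anchored thermal performance curve.

Pools each simulated individual's maximal sprint velocity per test
temperature, anchors the curve at zero velocity at the tolerance
limits, and reports predicted performance as a percentage of maximum —
the scale used for the landscape performance model.
"""

import thermoscape as ts

cfg = ts.TraitSimConfig(seed=42)
trials = ts.simulate_sprint_data(cfg)
points = ts.pooled_points(ts.max_velocities_by_temperature(trials))

curve = ts.fit_performance_curve(
    points, anchor_low=cfg.t_low, anchor_high=cfg.t_high,
    basis_dimension=5, smoothing=0.1,
)
print(f"fitted on {len(points)} (temperature, velocity) points")
print(f"peak predicted velocity {curve.p_max:.3f} m/s at {curve.argmax_T:.1f} °C "
      f"(generator's true optimum: {cfg.t_opt:.1f} °C)")

print("\npredicted performance (% of maximum):")
for t in (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 39.0):
    print(f"  {t:5.1f} °C -> {float(curve.performance_percent(t)):5.1f} %")
print("0% at the tolerance limits by construction; hours above 80% count "
      "toward the high-performance fraction.")
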