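"""Uncertainty of a single measurement set, Monte Carlo vs analytic.

For the dummy-bar setup, sweeps the rotation angle and propagates the
default noise model into the estimated moment twice over: empirically
(2,000 simulate-estimate replicates per angle) and analytically (first-
order delta method through M = M_total·|dCoM| / (2 sin(theta/2))).  At
the quarter turn it also prints the one-factor-at-a-time breakdown.
"""

from segmoment import NoiseModel, dummy_bar_model, monte_carlo

model = dummy_bar_model()
noise = NoiseModel()

print("theta    MC SD      analytic SD   relative SD")
for i, theta in enumerate([30.0, 60.0, 90.0, 135.0, 180.0]):
    rep = monte_carlo(model, theta, noise, n_reps=2000, seed=100 + i)
    print(f"{theta:5.0f}  {rep.mc_sd_kgcm:7.3f}    {rep.analytic_sd_kgcm:7.3f} kg·cm"
          f"   {rep.mc_relative_sd_pct:5.2f} %")

rep = monte_carlo(model, 90.0, noise, n_reps=2000, seed=7, breakdown=True)
print("\nper-source relative SD at 90 deg (one factor at a time):")
for source, pct in rep.breakdown_pct.items():
    print(f"  {source:9s} {pct:5.2f} %")
print(f"  combined  {rep.mc_relative_sd_pct:5.2f} %")

# Precision improves toward the half turn (the chord gain 2 sin(theta/2)
# peaks there); with the default noise magnitudes the angle record is the
# dominant error source at small angles, the support digitization at
# large ones, and the scale noise is nearly negligible throughout.
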