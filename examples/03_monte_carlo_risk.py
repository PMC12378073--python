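"""Probabilistic risk: Monte Carlo propagation of input uncertainty.

Draws 10,000 iterations with zero-truncated normal concentrations and a
lognormal milk intake rate, forms the HQ distribution per analyte and the
HI across analytes, and reads off the 95th percentile - the conventional
probabilistic risk statistic - plus a rank-correlation sensitivity
ranking of the inputs.
"""

from bmrisk import DEFAULT_SPECS, DistributionSpec, SimulationConfig, risk_verdict, simulate_hq

config = SimulationConfig(
    concentration={
        "MEL": DistributionSpec("normal", 114.0, 18.5, lower=0.0),
        "CYA": DistributionSpec("normal", 147.0, 28.7, lower=0.0),
    },
    fir=DistributionSpec("lognormal", -0.7, 0.5),  # log-space mean/sd, mL/kg/day
    n_iterations=10_000,
    seed=1234,
)
result = simulate_hq(config, DEFAULT_SPECS)

for analyte, summary in sorted(result.per_analyte.items()):
    print(
        f"{analyte}: mean HQ {summary.mean:.4f}, P95 HQ {summary.p95:.4f}, "
        f"P(HQ > 1) = {summary.exceedance_prob:.4f}"
    )
print(f"HI : P95 {result.hi.p95:.4f}, P(HI > 1) = {result.hi.exceedance_prob:.4f}")

print("\nSensitivity of HI (contribution to variance):")
for entry in result.hi.sensitivity:
    print(
        f"  {entry.variable:<20} rho = {entry.rank_correlation:+.3f}  "
        f"contribution = {entry.contribution:.3f}"
    )

verdict = risk_verdict(result)
print(f"\nVerdict: {verdict['classification']}")
print(
    "A P95 HQ below 1 means that even at the upper tail of the simulated\n"
    "exposure distribution the dose stays under the tolerable daily intake."
)
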