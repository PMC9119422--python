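"""Assess SNP saturation of a strain over a downsampling series.

Generates a series that reaches its plateau and one truncated mid-rise;
prints the damped-increase ratios R and the two-condition verdicts.
"""

import numpy as np

from snpsat.saturation import evaluate_series
from snpsat.synthetic import SimulationScenario, StrainSpec, simulate_saturation_series

fractions = np.array([0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0])
schedule = tuple((fractions * 2e7).astype(int))
scenario = SimulationScenario(
    seed=0, strains=[StrainSpec("s", 30_000, 1.0, 400, mu=200.0, sigma=10.0)]
)

levels, counts = simulate_saturation_series(scenario, "s", schedule=schedule, full_depth=200)
res = evaluate_series("s", levels, counts)
print("full series counts:", counts.astype(int).tolist())
print("R:", np.round(res.ratios, 3).tolist())
print(f"saturated: {res.saturated}; saturated SNP number: {res.saturated_snp_count}")

lv2, ct2 = simulate_saturation_series(
    scenario, "s", schedule=schedule[:3], full_depth=200, level_max=schedule[-1]
)
res2 = evaluate_series("s", lv2, ct2)
print("truncated series counts:", ct2.astype(int).tolist())
print(f"saturated: {res2.saturated}; reasons: {res2.reasons}")
print("a series cut short of its plateau keeps a large final R, so no verdict")
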