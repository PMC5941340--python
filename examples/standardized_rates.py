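"""Direct age standardization and the yearly incidence-rate series.

Standardization weights each year's age-specific rates by a fixed reference
population, making rates comparable across years even as the cohort ages.
"""

from crcclaims import (
    ReferencePopulation,
    SimulationConfig,
    direct_standardized_rate,
    rate_series,
    run_ascertainment,
    simulate,
)

# hand-checkable example: stratum rates 10 and 30 per 100,000, weights 1:3
ref = ReferencePopulation((("20-49", 20, 49), ("50+", 50, 200)), (250.0, 750.0))
rate = direct_standardized_rate([10, 30], [100_000, 100_000], ref)
print(f"two-stratum standardized rate: {rate:.1f} per 100,000 (0.25*10 + 0.75*30)")

dataset, _ = simulate(SimulationConfig(n_persons=20_000), seed=7)
cases = run_ascertainment(dataset, "A3")
series = rate_series(cases, dataset.persons, period=dataset.period)
print(series.round(1).to_string(index=False))
# Partial fiscal years at either end are dropped; the series covers 2001-2009.
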