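"""Characteristics of treated cases: concordant versus newly captured.

For each stratum (sex, age band, deprivation quintile, site) the table gives
the stratum's share of its concordance group and the proportions receiving
surgery and chemo/radiotherapy within that stratum and group, with Wald 95%
confidence intervals.
"""

from crcclaims import (
    SimulationConfig,
    build_table2,
    classify,
    run_ascertainment,
    simulate,
)

dataset, _ = simulate(SimulationConfig(n_persons=20_000), seed=7)
cases = run_ascertainment(dataset, "A3")
results = classify(cases, dataset.registry, {})
table = build_table2(cases, results, dataset.persons)

cols = ["section", "stratum", "concordant_n", "concordant_pct", "newly_captured_n", "newly_captured_pct"]
print(table[cols].round(1).to_string(index=False))
# Under the default capture model (younger, higher-SES cases less likely to
# reach the registry) the newly-captured column skews toward the young and
# the privileged quintiles.
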