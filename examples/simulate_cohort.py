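"""Generate a synthetic linked claims cohort and inspect its structure.

The simulator emulates a single-payer linkage: person demographics, physician
billing claims, hospital admissions, and a tumor registry that captures cases
principally through hospitalization. Ground truth is returned alongside.
"""

from crcclaims import SimulationConfig, simulate

config = SimulationConfig(n_persons=20_000)
dataset, truth = simulate(config, seed=7)

n_cases = int(truth["is_case"].sum())
print(f"persons:            {len(dataset.persons):>7}")
print(f"billing claims:     {len(dataset.billing):>7}")
print(f"hospital admissions:{len(dataset.admissions):>7}")
print(f"registry cases:     {len(dataset.registry):>7}")
print(f"true incident cases:{n_cases:>7}")
print(f"  hospitalized:     {int(truth['hospitalized'].sum()):>7}")
print(f"  registry-captured:{int(truth['registry_captured'].sum()):>7}")

# The gap between true cases and registry cases is the undercount a
# claims-based algorithm is built to close: outpatient-managed cases rarely
# reach a hospitalization-driven registry.
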