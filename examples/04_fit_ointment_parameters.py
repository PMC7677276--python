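"""Recover ointment parameters from noisy synthetic aqueous-humor data.

Generates a synthetic observed dataset from the fluorometholone ointment
model (truth: Higuchi constant 2.7e-6, application time 5 h) with 10%
multiplicative noise, then fits both parameters by bounded least squares
with Latin-hypercube multi-starts and prints the recovered values.
"""

from ocupbpk import fit_ointment, preset
from ocupbpk.synthetic import generate_synthetic_observed

scenario = preset("flm_table1")
observed = generate_synthetic_observed(
    scenario,
    compartment="aqueous_humor",
    sample_times_h=[0.5, 1, 2, 3, 4, 6, 8, 12, 18, 24],
    noise_cv=0.10,
    seed=7,
)

result = fit_ointment(
    observed.frame,
    scenario,
    free_params=("higuchi_constant", "application_time"),
    n_starts=5,
    seed=0,
)

truth = {"higuchi_constant": 2.7e-6, "application_time": 5.0}
print(f"converged: {result.converged}   weighted RSS: {result.objective:.4g}")
for name, value in result.parameters.items():
    err = 100 * abs(value - truth[name]) / truth[name]
    print(f"{name:25s} fitted {value:.3g}  (truth {truth[name]:.3g}, error {err:.1f}%)")
# With 10 sampling times and 10% noise both parameters are identifiable:
# the release constant scales the whole profile while the application time
# sets when the reservoir cuts off.
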