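"""Simulate one typical subject under the labeled bedaquiline regimen.

Builds the typical male black DS-TB patient, runs the labeled regimen
(400 mg QD x 14 days, then 200 mg thrice weekly for 22 weeks) and prints the
exposure metrics used to compare regimens.
"""

from bdqsim import (
    CovariateSet,
    labeled_regimen,
    load_default_parameters,
    population_exposures,
    typical_parameters,
)

params = load_default_parameters()
subject = typical_parameters(params.theta, CovariateSet("black", "male", "DS_TB"))
regimen = labeled_regimen()

metrics = population_exposures([subject], regimen).iloc[0]

print(f"regimen: {regimen.name}  ({regimen.n_events} doses, "
      f"{regimen.total_dose:.0f} mg over {regimen.duration / 24:.0f} days)")
print(f"Cmax            = {metrics.cmax:8.3f} ug/mL  at day {metrics.t_at_cmax / 24:.1f}")
print(f"cumulative AUC  = {metrics.cumulative_auc:8.1f} ug.h/mL (to 24 h post final dose)")
print(f"daily AUC (EOT) = {metrics.eot_daily_auc:8.2f} ug.h/mL (final week / 7)")
print()
print("The peak falls in the 14th dosing day, after the last 400 mg loading")
print("dose; later 200 mg TIW doses never exceed it.  AUCs are exact")
print("integrals of the linear compartment system, not quadrature.")
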