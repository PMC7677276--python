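"""One-at-a-time sensitivity of AH PK metrics to the ointment parameters.

Sweeps application surface area (25-100% of the cornea), application time
(1-7 h) and the Higuchi release constant, printing the PK metric table for
each sweep.  Application SA and the release constant drive Cmax and AUC;
application time mainly shifts Tmax.
"""

from ocupbpk import preset, psa_sweep

scenario = preset("flm_table1")
cornea_sa = scenario.physiology.cornea_surface_area

for parameter, values in [
    ("application_surface_area", [f * cornea_sa for f in (0.25, 0.5, 0.75, 1.0)]),
    ("application_time", [1, 3, 5, 7]),
    ("higuchi_constant", [1e-6, 2.7e-6, 5e-6, 1e-5]),
]:
    result = psa_sweep(scenario, parameter, values)
    print(f"\n== {parameter} ==")
    frame = result.frame().copy()
    frame["cmax_ng_per_mL"] = frame.pop("cmax_mg_per_mL") * 1e6
    frame["auc_ng_h_per_mL"] = frame.pop("auc_mg_h_per_mL") * 1e6
    print(frame.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
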