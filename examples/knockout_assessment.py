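"""Quantify what each gut region and transport process contributes.

Applies a few representative in silico knockouts (indicator gating of
passive diffusion or carrier-mediated transport) and reports, per dose,
the fractional loss of blood BHB exposure (AUC_fraction = 1 - AUC_ko/AUC_full)
and the displacement of the concentration peak (Tmax shift).  AUC_fraction
near 1 means the knocked-out route carried essentially all absorption;
near 0, none; negative values mean the knockout re-routed material to more
efficient sites.  The distal-gut and all-active knockouts remove a larger
fraction at the high dose — the dose-dependent absorption pattern.
"""

import ketoflux as kf
from ketoflux.assess import assess_knockouts
from ketoflux.knockouts import get_set

model = kf.build_model()
sets = [get_set(i) for i in (1, 6, 12, 13, 15)]
report = assess_knockouts(model, sets, doses=(192.0, 573.0), t_grid=kf.default_grid(6.0, 0.02))

cols = ["set_id", "variant_ids", "dose_mg_per_kg", "auc_fraction", "tmax_shift"]
print(report[cols].round(2).to_string(index=False))

cell = report.set_index(["set_id", "dose_mg_per_kg"])["auc_fraction"]
print(
    "\nall-active knockout (set 13): "
    f"{cell[13, 192.0]:.2f} at 192 mg/kg vs {cell[13, 573.0]:.2f} at 573 mg/kg"
)
print(
    "distal-gut knockout (set 15):  "
    f"{cell[15, 192.0]:.2f} at 192 mg/kg vs {cell[15, 573.0]:.2f} at 573 mg/kg"
)
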