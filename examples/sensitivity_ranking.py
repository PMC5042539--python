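"""Rank model parameters by their local influence on the blood BHB curve.

Computes normalized sensitivities (elasticities) S_p(t) = dC/dp * p/C by
central finite differences at the 192 mg/kg dose, summarized as the RMS over
the 6-hour curve.  An RMS of 1 means a 1% parameter change moves the curve
by about 1% — the blood volume sits there exactly, since concentration is
amount over volume.  Parameters feeding minor routes rank near zero.
"""

import ketoflux as kf
from ketoflux.calibrate import sensitivity

fixture = kf.default_fixture()
table = sensitivity(
    fixture,
    [
        "physiology.blood_volume_L",
        "gut.upper_proximal.passive_k.ester",
        "gut.upper_proximal.transit_k",
        "gut.upper_distal.apical_mct1.vmax",
        "transport.blood_to_tissues.BHB.vmax",
        "liver.endogenous_acac_rate",
        "feedback.ic50",
        "gut.lower_proximal.apical_smct1.vmax",
    ],
    dose_mg_per_kg=192.0,
    t_grid=kf.default_grid(6.0, 0.1),
)
print(table.round(4).to_string(index=False))
print("\nhighest-leverage parameter:", table.iloc[0]["parameter"])
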