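"""Sensitivity of accumulation pattern to the transport environment.

Sweeps alpha from 0.5 to 30 (via the interstitial hydraulic
conductivity at fixed cfc and R; the scaled solution depends only on
cfc*p_v and alpha) and prints, per combination: the central IFP/MVP
ratio, the average accumulation at an uptake-phase horizon relative to
peak plasma, the outer-shell mass fraction, and the uniform-versus-
peripheral regime label.
"""

import ittm
from ittm.sweep import SweepSpec

cfc, radius = 2.5e-5, 0.5
alphas = (0.5, 1.0, 3.0, 10.0, 30.0)

spec = SweepSpec(
    radius=(radius,),
    cfc=(cfc,),
    k_int=tuple(cfc * (radius / a) ** 2 for a in alphas),
    p_v=(8.0,),
    plasma=ittm.PlasmaDecayModel(c0=11.2, t_half=38.0),
    horizon_hr=8.0,   # uptake phase, before peri-tumoral washout
    shell=0.2,
)

result = ittm.run_sensitivity_sweep(spec)
cols = ["alpha", "ifp_ratio", "cbar_rel", "peripheral_fraction", "regime"]
print(result.table[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# Low-alpha tumors (small, permeable matrix, weak filtration) keep IFP
# well below MVP, accumulate liposomes fastest, and fill uniformly; the
# distribution turns rim-dominated once alpha exceeds ~3.
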