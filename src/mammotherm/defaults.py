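"""Default parameter set for the breast thermography model.

Healthy-tissue, blood and environment values are the study conditions:
k = 0.48 W/(m K), core temperature 309.5 K on the chest wall, ambient air
293 K, perfusion rate 1e-4 1/s with blood at 1100 kg/m^3 and 3300 J/(kg K),
h_f = 15 W/(m^2 K), sigma = 5.69e-8 W/(m^2 K^4) (as given in the reference
parameter set, not the CODATA value), emissivity 0.98.  The blood and the
breast tissue share density and specific heat.  The arterial temperature
defaults to the ambient 293 K, matching the reference model's
identification of the two.

The tumor is modelled as tissue with elevated metabolic heat generation and
perfusion.  The defaults below were fixed once by calibrating the magnitude
of the tumor-induced surface-dT increment over the tumor-free baseline to
~0.5 degC (the centre of the 0.2-0.8 degC band spanned by the published
estimation charts) at the reference scenario R1 = 60 mm, R2 = 3 mm, tumor
at (0, 10) mm; see docs/methods.md.
"""

from __future__ import annotations

from .bioheat import BoundarySpec, TissueProps
from .geometry import HEALTHY, TUMOR

# Healthy breast tissue.
K_TISSUE = 0.48          # W/(m K)
RHO_TISSUE = 1100.0      # kg/m^3 (shared with blood)
C_TISSUE = 3300.0        # J/(kg K) (shared with blood)
OMEGA_B = 1e-4           # 1/s
T_ARTERIAL = 293.0       # K (identified with ambient in the reference model)

# Environment / boundary.
T_CORE = 309.5           # K, chest-wall (flat base) temperature
T_AMBIENT = 293.0        # K
H_CONV = 15.0            # W/(m^2 K)
SIGMA_SB = 5.69e-8       # W/(m^2 K^4)
EMISSIVITY = 0.98

# Tumor contrast (calibrated once; see module docstring).  The source
# density needed to move the skin signal by ~0.5 degC for a 3 mm tumor at
# 10 mm depth under this model is roughly an order of magnitude above
# physiological metabolic rates -- a sign that the published contrast
# magnitudes cannot arise from metabolic heat alone; see docs/methods.md.
Q_MET_TUMOR = 4.7e5      # W/m^3
OMEGA_B_TUMOR = 5e-4     # 1/s

DEFAULT_SPACING_MM = 0.5

DEFAULT_HEALTHY = TissueProps(
    k=K_TISSUE,
    rho=RHO_TISSUE,
    c=C_TISSUE,
    q_met=0.0,
    omega_b=OMEGA_B,
    rho_b=RHO_TISSUE,
    c_b=C_TISSUE,
    T_a=T_ARTERIAL,
)

DEFAULT_TUMOR = TissueProps(
    k=K_TISSUE,
    rho=RHO_TISSUE,
    c=C_TISSUE,
    q_met=Q_MET_TUMOR,
    omega_b=OMEGA_B_TUMOR,
    rho_b=RHO_TISSUE,
    c_b=C_TISSUE,
    T_a=T_ARTERIAL,
)

DEFAULT_BOUNDARY = BoundarySpec(
    h_f=H_CONV,
    epsilon=EMISSIVITY,
    sigma=SIGMA_SB,
    T_f=T_AMBIENT,
    T_core=T_CORE,
)


def default_props_by_region() -> dict:
    return {HEALTHY: DEFAULT_HEALTHY, TUMOR: DEFAULT_TUMOR}
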