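"""Unit constants and conversion factors.

Internal conventions: energies in MeV, distances in metres at API
boundaries (centimetres inside kernel math), activities in Bq.  Q and A
values are expressed in TBq only at the reporting boundary in
:mod:`qtransport.qsystem` -- that module is the single Bq->TBq
conversion site.
"""

# Energy and dose
MEV_TO_J = 1.602176634e-13
MEV_PER_G_TO_GY = 1.602176634e-10  # 1 MeV/g = 1.602e-13 J / 1e-3 kg

# Exposure: 1 roentgen of air kerma (W/e = 33.97 J/C, 2.58e-4 C/kg)
GY_AIR_PER_R = 8.76e-3

# Time
S_PER_H = 3600.0

# Activity
BQ_PER_TBQ = 1e12

# Electron rest mass
ELECTRON_MASS_MEV = 0.51099895
ANNIHILATION_PHOTON_MEV = 0.511

# Classical electron radius (cm) and Avogadro's number
R_E_CM = 2.8179403262e-13
N_AVOGADRO = 6.02214076e23
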