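# provenance: effective dose per unit exposure in free air, (e/X), for photons.
# Synthetic approximation of the published effective-dose-equivalent-per-exposure data
# (isotropic-irradiation-like response; effective dose per air kerma converted with
# 1 R = 8.76 mGy air kerma).  Smooth to ~10%; valid 0.005-10 MeV.
# units: energy_mev [MeV], sv_per_r [Sv/R]
# version: 1.0
energy_mev,sv_per_r
0.005,7.0e-6
0.01,3.5e-5
0.015,1.05e-4
0.02,3.0e-4
0.03,8.8e-4
0.04,1.62e-3
0.05,2.28e-3
0.06,2.80e-3
0.08,3.68e-3
0.10,4.20e-3
0.15,4.91e-3
0.20,5.34e-3
0.30,5.69e-3
0.40,5.96e-3
0.50,6.13e-3
0.662,6.31e-3
0.80,6.48e-3
1.00,6.66e-3
1.25,6.83e-3
1.50,6.92e-3
2.00,7.10e-3
3.00,7.36e-3
4.00,7.53e-3
5.00,7.71e-3
6.00,7.80e-3
8.00,8.06e-3
10.00,8.23e-3
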