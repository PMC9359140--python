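# provenance: Berger-form air kerma buildup coefficients, B(E, x) = 1 + a*x*exp(b*x)
# with x the optical depth (mean free paths).  Approximate compilation for point
# isotropic sources in air; adequate for the sub-0.02 mfp depths met at 1 m in air,
# where B - 1 < 3%.
# units: energy_mev [MeV], a [-], b [-]
# version: 1.0
energy_mev,a,b
0.005,0.10,0.02
0.01,0.50,0.05
0.02,1.50,0.08
0.03,2.50,0.10
0.05,4.00,0.10
0.10,3.00,0.10
0.20,2.40,0.08
0.50,1.70,0.06
1.00,1.20,0.05
2.00,0.90,0.04
5.00,0.55,0.03
10.00,0.40,0.02
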