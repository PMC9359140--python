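# provenance: mass attenuation and mass energy-absorption coefficients for dry air,
# approximate digitization of the standard photon cross-section compilations (NIST-style
# tables); values accurate to a few percent over 0.005-10 MeV.
# units: energy_mev [MeV], mu_rho [cm^2/g] (total with coherent), mu_en_rho [cm^2/g]
# version: 1.0
energy_mev,mu_rho,mu_en_rho
0.005,40.27,39.75
0.01,5.120,4.742
0.015,1.614,1.334
0.02,0.7779,0.5389
0.03,0.3538,0.1537
0.04,0.2485,0.0683
0.05,0.2080,0.0406
0.06,0.1875,0.0305
0.08,0.1662,0.0243
0.10,0.1541,0.0234
0.15,0.1356,0.0250
0.20,0.1233,0.0268
0.30,0.1067,0.0288
0.40,0.0954,0.0296
0.50,0.0868,0.0297
0.60,0.0804,0.0296
0.80,0.0707,0.0289
1.00,0.0636,0.0278
1.25,0.0569,0.0266
1.50,0.0518,0.0255
2.00,0.0445,0.0234
3.00,0.0358,0.0205
4.00,0.0308,0.0186
5.00,0.0275,0.0173
6.00,0.0252,0.0163
8.00,0.0223,0.0150
10.00,0.0204,0.0145
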