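# provenance: mass attenuation and mass energy-absorption coefficients for liquid water,
# approximate digitization of the standard photon cross-section compilations (NIST-style
# tables); values accurate to a few percent over 0.005-10 MeV.
# units: energy_mev [MeV], mu_rho [cm^2/g] (total with coherent), mu_en_rho [cm^2/g]
# version: 1.0
energy_mev,mu_rho,mu_en_rho
0.005,41.85,41.30
0.01,5.329,4.944
0.015,1.673,1.374
0.02,0.8096,0.5503
0.03,0.3756,0.1557
0.04,0.2683,0.0695
0.05,0.2269,0.0422
0.06,0.2059,0.0319
0.08,0.1837,0.0262
0.10,0.1707,0.0255
0.15,0.1505,0.0277
0.20,0.1370,0.0297
0.30,0.1186,0.0319
0.40,0.1061,0.0328
0.50,0.0969,0.0330
0.60,0.0896,0.0329
0.80,0.0786,0.0321
1.00,0.0707,0.0309
1.25,0.0632,0.0296
1.50,0.0575,0.0283
2.00,0.0494,0.0260
3.00,0.0397,0.0227
4.00,0.0340,0.0206
5.00,0.0303,0.0191
6.00,0.0277,0.0180
8.00,0.0243,0.0166
10.00,0.0222,0.0157
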