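# provenance: CSDA ranges of electrons in air and in liquid water, approximate
# digitization of the standard stopping-power compilations (ESTAR-style tables);
# accurate to a few percent over 0.01-5 MeV.
# units: energy_mev [MeV], range_air [g/cm^2], range_water [g/cm^2]
# version: 1.0
energy_mev,range_air,range_water
0.01,2.88e-4,2.52e-4
0.015,5.80e-4,5.10e-4
0.02,9.80e-4,8.57e-4
0.03,2.00e-3,1.76e-3
0.04,3.31e-3,2.92e-3
0.05,4.89e-3,4.32e-3
0.06,6.70e-3,5.93e-3
0.08,1.10e-2,9.75e-3
0.10,1.61e-2,1.431e-2
0.15,3.16e-2,2.82e-2
0.20,5.01e-2,4.49e-2
0.30,9.35e-2,8.42e-2
0.36,1.21e-1,1.09e-1
0.40,1.36e-1,1.23e-1
0.50,1.95e-1,1.77e-1
0.60,2.57e-1,2.34e-1
0.70,3.20e-1,2.92e-1
0.80,3.86e-1,3.53e-1
1.00,4.80e-1,4.37e-1
1.25,6.23e-1,5.67e-1
1.50,7.66e-1,6.97e-1
2.00,1.075,9.79e-1
2.50,1.380,1.258
3.00,1.660,1.514
4.00,2.240,2.040
5.00,2.800,2.550
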