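# provenance: published Monte-Carlo dose-rate coefficients, Q values and
# A1/A2 transport limits for a control group of ten tabulated radionuclides and
# twelve medical radionuclides without tabulated limits.  Shipped as a validation
# fixture; empty cells were not printed in the source tables.  The daughter column
# is recorded verbatim from the source (including its "Po-212" entry for At-211,
# physically Po-211).  "consistent" flags rows whose printed coefficient -> Q
# arithmetic chain is internally consistent to 1% for every printed pathway.
# units: e_pt, e_b [Sv/(Bq h)]; e_inh [Sv/Bq]; h_skin [Sv m^2/(TBq s)];
#        q_* and a1, a2 [TBq]
# version: 1.0
nuclide,group,daughter,decay_mode,e_pt,e_b,e_inh,h_skin,q_a,q_b,q_c,q_d,a1,a2,consistent
Be-7,control,,EC,4.78e-15,5.48e-19,5.20e-11,9.64e-03,2.09e+01,1.82e+06,9.62e+02,2.90e+00,2.09e+01,2.90e+00,True
Na-22,control,,EC B+,1.89e-13,3.69e-13,2.00e-09,4.02e-02,5.29e-01,2.71e+00,2.50e+01,6.96e-01,5.29e-01,5.29e-01,True
Na-24,control,,B-,2.87e-13,4.05e-12,2.90e-10,3.99e-02,3.48e-01,2.47e-01,1.72e+02,7.02e-01,2.47e-01,2.47e-01,True
Ca-47,control,Sc-47,B-,9.61e-14,1.94e-12,2.83e-09,7.92e-02,1.04e+00,5.16e-01,1.77e+01,3.54e-01,5.16e-01,3.54e-01,True
Co-58,control,,EC B+,1.01e-13,1.12e-14,2.00e-09,6.97e-03,9.89e-01,8.95e+01,3.57e+01,4.01e+00,9.89e-01,9.89e-01,False
Co-60,control,,B-,1.68e-13,3.32e-15,2.90e-08,3.03e-02,5.95e-01,3.01e+02,2.07e+00,9.23e-01,5.95e-01,5.95e-01,False
Sr-82,control,Rb-82,EC,1.05e-13,3.55e-12,1.00e-08,6.97e-02,9.53e-01,2.82e-01,5.00e+00,4.02e-01,2.82e-01,2.82e-01,True
Y-90,control,,B-,1.22e-19,3.73e-12,1.60e-09,3.77e-02,8.21e+05,2.68e-01,3.30e+01,7.43e-01,2.68e-01,2.68e-01,False
Cs-137,control,Ba-137m,B-,6.36e-14,4.02e-13,4.80e-09,4.20e-02,1.57e+00,2.49e+00,7.46e+00,6.66e-01,1.57e+00,6.66e-01,False
At-211,control,Po-212,A EC,4.65e-15,6.42e-15,1.10e-07,1.20e-04,2.15e+01,1.56e+02,4.55e-01,2.33e+02,2.15e+01,4.55e-01,True
Cu-61,other,,EC B+,8.90e-14,9.21e-13,1.20e-10,2.50e-02,1.12e+00,1.09e+00,4.17e+02,1.12e+00,1.09e+00,1.09e+00,True
As-71,other,,EC B+,5.51e-14,9.15e-14,5.00e-10,1.67e-02,1.82e+00,1.09e+01,1.00e+02,1.67e+00,1.82e+00,1.67e+00,True
Se-72,other,As-72,EC,1.64e-13,7.20e-12,9.20e-10,6.72e-02,6.09e-01,1.39e-01,5.43e+01,4.17e-01,1.39e-01,1.39e-01,True
Nd-140,other,Pr-140,EC,3.17e-15,2.11e-12,,1.92e-02,3.16e+01,4.75e-01,,1.46e+00,4.75e-01,4.75e-01,True
Tb-152,other,,EC B+,1.26e-13,1.33e-12,,9.98e-03,7.94e-01,7.53e-01,,2.81e+00,7.53e-01,7.53e-01,True
Tb-155,other,,EC,1.90e-14,8.06e-16,2.50e-10,7.36e-03,5.27e+00,1.24e+03,2.00e+02,3.81e+00,5.27e+00,3.81e+00,True
Tb-156,other,,EC,1.67e-13,3.09e-14,1.40e-09,2.27e-02,5.99e-01,3.24e+01,3.57e+01,1.23e+00,5.99e-01,5.99e-01,True
Tb-161,other,,B-,1.41e-14,5.37e-15,1.20e-09,3.69e-02,7.11e+00,1.86e+02,4.17e+01,7.58e-01,7.11e+00,7.58e-01,True
Tm-166,other,,EC B+,1.61e-13,8.87e-14,2.80e-10,1.65e-02,6.23e-01,1.13e+01,1.79e+02,1.70e+00,6.23e-01,6.23e-01,True
Yb-166,other,Tm-166,EC,1.70e-13,9.77e-14,1.19e-09,1.96e-02,5.88e-01,1.02e+01,4.20e+01,1.43e+00,5.88e-01,5.88e-01,True
Tb-149,other,,EC B+ A,1.17e-13,4.17e-13,3.10e-09,1.21e-02,8.56e-01,2.40e+00,1.61e+01,2.31e+00,8.56e-01,8.56e-01,True
Bi-213,other,Po-213.Tl-209,EC B+ A,1.89e-13,2.20e-12,4.10e-08,4.55e-02,5.29e-01,4.54e-01,1.22e+00,6.15e-01,4.54e-01,4.54e-01,True
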