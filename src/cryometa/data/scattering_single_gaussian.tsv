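# single-Gaussian electron scattering parameters, v1
# least-squares fit of A*exp(-B s^2) to the 5-Gaussian neutral-atom
# factors over s in [0, 0.5] A^-1 (see forward.fit_single_gaussian_factors)
# element  weight  variance_nm2
H	4.963815852e-01	4.791582154e-03
C	2.349102557e+00	4.865041032e-03
N	2.097582993e+00	3.781759733e-03
O	1.899415828e+00	3.076121184e-03
P	5.048757669e+00	5.874940385e-03
S	4.809312850e+00	5.012121613e-03
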