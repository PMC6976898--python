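tissue	wavelength_nm	mu_a_per_mm	mu_s_per_mm	g	n
skin	700	0.042	14.3	0.9	1.4
skin	800	0.035	15.9	0.9	1.4
skin	900	0.031	16.8	0.9	1.4
skin	1064	0.031	16.8	0.9	1.4
fatty	700	0.099	12.2	0.9	1.4
fatty	800	0.095	11.3	0.9	1.4
fatty	900	0.096	10.2	0.9	1.4
fatty	1064	0.097	9.09	0.9	1.4
fibrous	700	0.010	2.31	0.9	1.4
fibrous	800	0.016	1.91	0.9	1.4
fibrous	900	0.064	1.63	0.9	1.4
fibrous	1064	0.076	1.30	0.9	1.4
milk	1064	0.02	7	0.7	1.338
gelatin	1064	0.012	0.05	0.85	1.5
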