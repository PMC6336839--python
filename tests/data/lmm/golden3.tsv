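term	estimate	se	df	t	p	sigma2_donor	sigma2_resid
(Intercept)	0.974306880325244	0.57604267630145	13.9251244157426	1.69137968488879	0.113012099182653	1.18567574173583	0.394167720203286
diagnosiscase	0.57499739834506	0.681097310152884	14.8418096000444	0.844222095394845	0.411946848302491	1.18567574173583	0.394167720203286
cell_typeneuronal	0.219257500000002	0.313913889547471	14.0000000230091	0.698463837697904	0.496326396217156	1.18567574173583	0.394167720203286
sexmale	-0.236971726718888	0.604175893443792	11.9999999461798	-0.392223074919712	0.701770498858658	1.18567574173583	0.394167720203286
ancestry1	-0.221386474989267	0.408723904379229	11.9999999474701	-0.541652867907273	0.597971011352499	1.18567574173583	0.394167720203286
diagnosiscase:cell_typeneuronal	0.718848499999998	0.443941280015323	14.0000000228087	1.61924230153859	0.127694867402013	1.18567574173583	0.394167720203286
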