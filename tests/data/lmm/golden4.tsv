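term	estimate	se	df	t	p	sigma2_donor	sigma2_resid
(Intercept)	1.02510355348397	0.546488445109454	14.0277326922923	1.87580096643884	0.0816480053004298	0.979310579327421	0.372297276964564
diagnosiscase	0.385814273115431	0.585430891293616	15.7341413600733	0.65902616150457	0.519408156907353	0.979310579327421	0.372297276964564
cell_typeneuronal	1.123812125	0.305080840501564	14.0000000554554	3.68365356261773	0.00245553496014325	0.979310579327421	0.372297276964564
sexmale	0.744044919740311	0.577255696515101	11.9999998709944	1.28893473764247	0.221714459040086	0.979310579327421	0.372297276964564
ancestry1	0.398872114641236	0.352556236693011	11.9999998716836	1.13137160296091	0.280002328356253	0.979310579327421	0.372297276964564
diagnosiscase:cell_typeneuronal	0.321526875000003	0.431449462257495	14.0000000553855	0.745224882927567	0.468463089406599	0.979310579327421	0.372297276964564
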