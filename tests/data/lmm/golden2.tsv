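term	estimate	se	df	t	p	sigma2_donor	sigma2_resid
(Intercept)	0.863242508620406	0.423411188190056	22.8219648095497	2.03878058185114	0.0532194094775705	0.138010211368135	1.01092468407141
diagnosiscase	1.01630779815817	0.599258436711723	22.8055701459845	1.69594241131572	0.103507590660591	0.138010211368135	1.01092468407141
cell_typeneuronal	0.678008124999998	0.50272375219185	13.9999996500955	1.34866936770725	0.19885628203885	0.138010211368135	1.01092468407141
sexmale	0.649975516927545	0.513301712758222	11.9999999536837	1.26626407193326	0.22944768902203	0.138010211368135	1.01092468407141
ancestry1	-0.118897431045834	0.232526617396283	11.9999999524585	-0.511328261586513	0.61839875417914	0.138010211368135	1.01092468407141
diagnosiscase:cell_typeneuronal	0.795085125000002	0.710958748476805	13.9999996520246	1.11832806995263	0.282249697672858	0.138010211368135	1.01092468407141
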