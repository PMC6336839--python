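term	estimate	se	df	t	p	sigma2_donor	sigma2_resid
(Intercept)	0.969530528408517	0.529601817268578	15.5618765744868	1.83067825070705	0.0863652674996131	1.17604946502973	0.584194713554436
diagnosiscase	2.14812913336112	0.688077362170258	16.3109212914184	3.12192967166617	0.00645148501220479	1.17604946502973	0.584194713554436
cell_typeneuronal	0.571510749999999	0.382163156765025	14.0000000904363	1.49546270979595	0.15699189081091	1.17604946502973	0.584194713554436
sexmale	0.519164920417918	0.625721194162743	11.9999998024976	0.829706465533097	0.422903596143831	1.17604946502973	0.584194713554436
ancestry1	0.236183982498446	0.365253806076823	11.999999803585	0.646629764205031	0.530045517817965	1.17604946502973	0.584194713554436
diagnosiscase:cell_typeneuronal	-0.204214124999998	0.540460319336413	14.0000000904993	-0.377852208004346	0.711207395395062	1.17604946502973	0.584194713554436
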