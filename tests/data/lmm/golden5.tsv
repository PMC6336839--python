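term	estimate	se	df	t	p	sigma2_donor	sigma2_resid
(Intercept)	0.0503417498796408	0.60035050923957	13.3495199181022	0.0838539305037083	0.934417015758111	0.864013957945154	0.30662211841723
diagnosiscase	2.43374589970281	0.628497835706266	14.573280532538	3.87232184653098	0.00157915278307442	0.864013957945154	0.30662211841723
cell_typeneuronal	0.478347875	0.276867350195554	14.0000003239898	1.72771500381731	0.106022922223149	0.864013957945154	0.30662211841723
sexmale	0.89374009076426	0.590773992722256	11.9999992180044	1.51282910516415	0.156205385413542	0.864013957945154	0.30662211841723
ancestry1	0.159470925022446	0.32030695262501	11.9999992212556	0.497869071262846	0.627574647102358	0.864013957945154	0.30662211841723
diagnosiscase:cell_typeneuronal	0.656126625000001	0.391549561624854	14.0000003238182	1.67571794047529	0.115973890435464	0.864013957945154	0.30662211841723
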