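donor_id,diagnosis,cell_type,sex,ancestry1,y
D01,case,neuronal,male,-0.120564,1.933238
D01,case,non_neuronal,male,-0.120564,1.310175
D02,case,neuronal,female,1.486142,4.707063
D02,case,non_neuronal,female,1.486142,3.605749
D03,case,neuronal,male,-0.282276,3.883195
D03,case,non_neuronal,male,-0.282276,1.849582
D04,case,neuronal,male,-0.576655,3.467093
D04,case,non_neuronal,male,-0.576655,2.219604
D05,case,neuronal,female,0.698762,2.166848
D05,case,non_neuronal,female,0.698762,-1.03918
D06,case,neuronal,female,0.093395,3.279748
D06,case,non_neuronal,female,0.093395,2.925588
D07,case,neuronal,male,-0.032406,4.931934
D07,case,non_neuronal,male,-0.032406,3.106897
D08,case,neuronal,female,-0.546208,1.744379
D08,case,non_neuronal,female,-0.546208,0.572371
D09,control,neuronal,male,-1.107691,1.726214
D09,control,non_neuronal,male,-1.107691,1.265467
D10,control,neuronal,male,-0.739152,2.102849
D10,control,non_neuronal,male,-0.739152,1.468815
D11,control,neuronal,male,1.92217,3.524717
D11,control,non_neuronal,male,1.92217,1.803536
D12,control,neuronal,female,-0.493458,3.807341
D12,control,non_neuronal,female,-0.493458,1.741575
D13,control,neuronal,female,0.074102,1.254251
D13,control,non_neuronal,female,0.074102,0.039156
D14,control,neuronal,female,1.009801,1.777507
D14,control,non_neuronal,female,1.009801,1.86115
D15,control,neuronal,male,-0.232737,4.315267
D15,control,non_neuronal,male,-0.232737,2.092145
D16,control,neuronal,male,-0.480534,2.384458
D16,control,non_neuronal,male,-0.480534,1.630263
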