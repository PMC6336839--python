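donor_id,diagnosis,cell_type,sex,ancestry1,y
D01,case,neuronal,female,-0.485661,6.559347
D01,case,non_neuronal,female,-0.485661,4.207073
D02,case,neuronal,male,0.200218,3.079684
D02,case,non_neuronal,male,0.200218,4.105623
D03,case,neuronal,female,-1.40924,2.858541
D03,case,non_neuronal,female,-1.40924,2.754808
D04,case,neuronal,male,-0.742408,3.173576
D04,case,non_neuronal,male,-0.742408,2.399651
D05,case,neuronal,female,-0.300981,2.534415
D05,case,non_neuronal,female,-0.300981,3.016578
D06,case,neuronal,male,0.123542,3.977421
D06,case,non_neuronal,male,0.123542,3.398719
D07,case,neuronal,male,1.59953,5.563085
D07,case,non_neuronal,male,1.59953,4.717282
D08,case,neuronal,male,0.6177,2.63557
D08,case,non_neuronal,male,0.6177,2.843532
D09,control,neuronal,female,-0.011264,0.968167
D09,control,non_neuronal,female,-0.011264,0.883325
D10,control,neuronal,female,1.646776,2.619554
D10,control,non_neuronal,female,1.646776,2.693117
D11,control,neuronal,female,-0.410831,0.221364
D11,control,non_neuronal,female,-0.410831,1.087049
D12,control,neuronal,female,0.831448,2.855449
D12,control,non_neuronal,female,0.831448,0.163518
D13,control,neuronal,female,0.972333,-0.538642
D13,control,non_neuronal,female,0.972333,-0.129672
D14,control,neuronal,male,-0.499104,1.058491
D14,control,non_neuronal,male,-0.499104,0.145364
D15,control,neuronal,male,-0.858831,3.538442
D15,control,non_neuronal,male,-0.858831,2.548359
D16,control,neuronal,male,-0.024395,3.55179
D16,control,non_neuronal,male,-0.024395,2.311469
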