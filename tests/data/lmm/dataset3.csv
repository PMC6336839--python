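donor_id,diagnosis,cell_type,sex,ancestry1,y
D01,case,neuronal,male,-1.631707,4.761604
D01,case,non_neuronal,male,-1.631707,2.854023
D02,case,neuronal,female,0.981203,3.033803
D02,case,non_neuronal,female,0.981203,0.756547
D03,case,neuronal,female,0.73351,1.632903
D03,case,non_neuronal,female,0.73351,1.42708
D04,case,neuronal,male,-0.04155,3.038201
D04,case,non_neuronal,male,-0.04155,2.222972
D05,case,neuronal,male,-0.044198,1.259731
D05,case,non_neuronal,male,-0.044198,-0.616856
D06,case,neuronal,female,-0.1876,1.73991
D06,case,non_neuronal,female,-0.1876,2.143551
D07,case,neuronal,female,-0.381125,2.059441
D07,case,non_neuronal,female,-0.381125,0.731928
D08,case,neuronal,female,-0.861109,1.979927
D08,case,non_neuronal,female,-0.861109,2.481427
D09,control,neuronal,female,-0.253871,1.633362
D09,control,non_neuronal,female,-0.253871,1.875104
D10,control,neuronal,female,0.165428,1.345627
D10,control,non_neuronal,female,0.165428,0.608585
D11,control,neuronal,male,1.197739,0.01747
D11,control,non_neuronal,male,1.197739,1.165613
D12,control,neuronal,male,-0.371768,1.533637
D12,control,non_neuronal,male,-0.371768,1.084861
D13,control,neuronal,male,1.28476,0.883925
D13,control,non_neuronal,male,1.28476,0.369224
D14,control,neuronal,female,0.130275,-0.238977
D14,control,non_neuronal,female,0.130275,-1.020833
D15,control,neuronal,male,-0.151966,-0.486888
D15,control,non_neuronal,male,-0.151966,-0.730338
D16,control,neuronal,female,1.27216,3.187928
D16,control,non_neuronal,female,1.27216,2.769808
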