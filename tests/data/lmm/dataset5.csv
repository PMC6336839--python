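donor_id,diagnosis,cell_type,sex,ancestry1,y
D01,case,neuronal,male,-0.062714,3.976282
D01,case,non_neuronal,male,-0.062714,3.982747
D02,case,neuronal,female,0.005122,3.487265
D02,case,non_neuronal,female,0.005122,1.377598
D03,case,neuronal,female,-1.000725,3.424182
D03,case,non_neuronal,female,-1.000725,3.201371
D04,case,neuronal,female,-0.07923,4.981491
D04,case,non_neuronal,female,-0.07923,3.741466
D05,case,neuronal,female,0.064856,1.710388
D05,case,non_neuronal,female,0.064856,0.842913
D06,case,neuronal,female,1.057895,2.460488
D06,case,non_neuronal,female,1.057895,1.110791
D07,case,neuronal,female,0.561483,5.360656
D07,case,non_neuronal,female,0.561483,4.282668
D08,case,neuronal,male,-0.430223,5.353798
D08,case,non_neuronal,male,-0.430223,3.1392
D09,control,neuronal,male,-0.115578,1.341171
D09,control,non_neuronal,male,-0.115578,-0.540875
D10,control,neuronal,female,-0.646123,0.702497
D10,control,non_neuronal,female,-0.646123,-0.086142
D11,control,neuronal,male,1.420096,1.475064
D11,control,non_neuronal,male,1.420096,1.613251
D12,control,neuronal,male,-1.707498,0.028624
D12,control,non_neuronal,male,-1.707498,0.197165
D13,control,neuronal,male,0.920868,2.320449
D13,control,non_neuronal,male,0.920868,1.111563
D14,control,neuronal,male,-0.358835,1.244468
D14,control,non_neuronal,male,-0.358835,1.561087
D15,control,neuronal,male,-0.168522,1.760585
D15,control,non_neuronal,male,-0.168522,1.254512
D16,control,neuronal,female,-1.295996,0.407878
D16,control,non_neuronal,female,-1.295996,0.343392
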