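donor_id,diagnosis,cell_type,sex,ancestry1,y
D01,case,neuronal,female,-0.134842,3.242711
D01,case,non_neuronal,female,-0.134842,0.159212
D02,case,neuronal,male,0.087537,2.794221
D02,case,non_neuronal,male,0.087537,2.665383
D03,case,neuronal,male,2.118328,3.906537
D03,case,non_neuronal,male,2.118328,3.991079
D04,case,neuronal,male,1.357064,4.233036
D04,case,non_neuronal,male,1.357064,1.967124
D05,case,neuronal,male,-0.603615,4.938123
D05,case,non_neuronal,male,-0.603615,2.960055
D06,case,neuronal,male,0.96656,4.321087
D06,case,non_neuronal,male,0.96656,0.927992
D07,case,neuronal,male,0.047437,3.195635
D07,case,non_neuronal,male,0.047437,1.947773
D08,case,neuronal,male,-0.84255,4.38342
D08,case,non_neuronal,male,-0.84255,4.611406
D09,control,neuronal,male,1.662607,0.588057
D09,control,non_neuronal,male,1.662607,0.775446
D10,control,neuronal,female,-0.23537,1.93622
D10,control,non_neuronal,female,-0.23537,0.403856
D11,control,neuronal,female,0.779057,1.544519
D11,control,non_neuronal,female,0.779057,2.175924
D12,control,neuronal,female,1.030049,2.169207
D12,control,non_neuronal,female,1.030049,-1.094933
D13,control,neuronal,male,1.780801,1.876417
D13,control,non_neuronal,male,1.780801,2.963377
D14,control,neuronal,female,-0.590481,2.009327
D14,control,non_neuronal,female,-0.590481,1.576974
D15,control,neuronal,male,-0.413797,1.969604
D15,control,non_neuronal,male,-0.413797,0.35767
D16,control,neuronal,female,0.008597,1.708439
D16,control,non_neuronal,female,0.008597,1.219411
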