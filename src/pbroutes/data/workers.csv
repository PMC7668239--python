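worker_id,blood_pb_ugdl,blood_below_lod,blood_lod_ugdl,glove_use
1,14.9,False,0.72,True
2,6.0,False,0.72,True
3,29.0,False,0.72,False
4,33.2,False,0.72,False
5,7.4,False,0.72,True
6,4.9,False,0.72,True
7,0.72,True,0.72,True
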