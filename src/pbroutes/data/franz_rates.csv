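mcf_id,interval_h,rate_ng_cm2_h
MCF1,2,0.97
MCF2,2,0.77
MCF3,2,1.09
MCF4,2,0.32
MCF1,4,0.47
MCF2,4,0.43
MCF3,4,0.54
MCF4,4,0.20
MCF1,24,0.11
MCF2,24,0.077
MCF3,24,0.14
MCF4,24,0.10
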