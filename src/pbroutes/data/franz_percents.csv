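mcf_id,compartment,time_h,percent
MCF1,donor,2,59.3
MCF2,donor,2,75.8
MCF3,donor,2,63.5
MCF4,donor,2,69.9
MCF1,donor,4,37.7
MCF2,donor,4,45.6
MCF3,donor,4,70.5
MCF4,donor,4,76.5
MCF1,donor,24,50.5
MCF2,donor,24,67.2
MCF3,donor,24,64.9
MCF4,donor,24,59.8
MCF1,skin,2,4.13
MCF2,skin,2,3.91
MCF3,skin,2,2.11
MCF4,skin,2,2.33
MCF1,skin,4,4.76
MCF2,skin,4,4.71
MCF3,skin,4,3.95
MCF4,skin,4,3.94
MCF1,skin,24,2.55
MCF2,skin,24,10.4
MCF3,skin,24,9.20
MCF4,skin,24,10.9
MCF1,receptor,2,0.001
MCF2,receptor,2,0.002
MCF3,receptor,2,0.003
MCF4,receptor,2,0.002
MCF1,receptor,4,0.001
MCF2,receptor,4,0.003
MCF3,receptor,4,0.003
MCF4,receptor,4,0.002
MCF1,receptor,24,0.001
MCF2,receptor,24,0.003
MCF3,receptor,24,0.004
MCF4,receptor,24,0.002
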