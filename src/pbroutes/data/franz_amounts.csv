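mcf_id,compartment,time_h,n,amount_ug_cm2
MCF1,matrix,0,12,290
MCF2,matrix,0,12,79.2
MCF3,matrix,0,12,97.8
MCF4,matrix,0,12,48.4
MCF1,donor,2,4,172
MCF2,donor,2,4,60.0
MCF3,donor,2,4,62.2
MCF4,donor,2,4,33.8
MCF1,donor,4,4,109.4
MCF2,donor,4,4,36.2
MCF3,donor,4,4,69.0
MCF4,donor,4,4,37.2
MCF1,donor,24,4,146.4
MCF2,donor,24,4,53.2
MCF3,donor,24,4,63.6
MCF4,donor,24,4,29.0
MCF1,skin,2,4,12.0
MCF2,skin,2,4,3.10
MCF3,skin,2,4,2.07
MCF4,skin,2,4,1.13
MCF1,skin,4,4,13.8
MCF2,skin,4,4,3.73
MCF3,skin,4,4,3.86
MCF4,skin,4,4,1.91
MCF1,skin,24,4,7.41
MCF2,skin,24,4,8.28
MCF3,skin,24,4,9.00
MCF4,skin,24,4,5.27
MCF1,receptor,2,4,0.00248
MCF2,receptor,2,4,0.00197
MCF3,receptor,2,4,0.00278
MCF4,receptor,2,4,0.000826
MCF1,receptor,4,4,0.00244
MCF2,receptor,4,4,0.00218
MCF3,receptor,4,4,0.00276
MCF4,receptor,4,4,0.00104
MCF1,receptor,24,4,0.00324
MCF2,receptor,24,4,0.00238
MCF3,receptor,24,4,0.00438
MCF4,receptor,24,4,0.00306
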