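worker_id,hand,site,dose_ug_cm2
1,left,palm,3.8
1,left,wrist,0.8
1,left,index,12
1,right,palm,4.5
1,right,wrist,1.4
1,right,index,15.3
2,left,palm,0.6
2,left,wrist,0.2
2,left,index,0.7
2,right,palm,0.8
2,right,wrist,0.2
2,right,index,0.9
3,left,palm,4.1
3,left,wrist,1.1
3,left,index,24.6
3,right,palm,8.0
3,right,wrist,0.8
3,right,index,32.4
4,left,palm,9.1
4,left,wrist,3.4
4,left,index,36.4
4,right,palm,13.8
4,right,wrist,3.0
4,right,index,48.4
5,left,palm,4.2
5,left,wrist,0.4
5,left,index,7.1
5,right,palm,2.3
5,right,wrist,0.6
5,right,index,9.5
6,left,palm,1.4
6,left,wrist,2.4
6,left,index,3.7
6,right,palm,0.9
6,right,wrist,3.1
6,right,index,6.5
7,left,palm,0.2
7,left,wrist,0.1
7,left,index,1.0
7,right,palm,0.52
7,right,wrist,0.6
7,right,index,4.6
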