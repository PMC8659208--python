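set,system,ligand,kd_micromolar,docking_score
training,4UIW,1,0.002,-9.0
training,5F1H,5,0.014,-9.2
training,5IGM,6,0.042,-6.7
training,5E9V,4,0.070,-4.8
training,6V14,8,0.082,-8.3
training,4XY8,2,0.397,-9.3
training,4Z6I,3,0.493,-7.9
training,6V0S,7,16,-4.5
test,9,9,0.0094,-9.4
test,10a,10,0.099,-5.3
test,10b,10,,-5.2
test,11,11,1.01,-7.4
test,12,12,17.0,-5.9
test,13,13,,-5.7
test,14,14,,-7.9
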