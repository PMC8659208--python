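system,replica,rmsd_angstrom
apo,1,2.53
apo,2,3.45
apo,3,2.40
4UIW,1,2.07
4UIW,2,2.56
4UIW,3,1.89
4XY8,1,4.25
4XY8,2,3.73
4XY8,3,4.17
4Z6I,1,2.75
4Z6I,2,2.63
4Z6I,3,3.44
5E9V,1,3.12
5E9V,2,2.67
5E9V,3,3.16
5F1H,1,1.94
5F1H,2,1.82
5F1H,3,2.87
5IGM,1,2.77
5IGM,2,2.41
5IGM,3,2.48
6V0S,1,1.83
6V0S,2,3.02
6V0S,3,3.39
6V14,1,2.41
6V14,2,1.87
6V14,3,2.12
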