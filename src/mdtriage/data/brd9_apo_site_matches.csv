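system,match_count
4UIW,3
4XY8,8
4Z6I,7
5E9V,26
5F1H,20
5IGM,15
6V0S,53
6V14,8
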