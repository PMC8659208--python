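set,system,replica,energy,unit
training,4UIW,1,-81.7,kcal/mol
training,4UIW,2,-85.3,kcal/mol
training,4UIW,3,-96.4,kcal/mol
training,5F1H,1,-75.7,kcal/mol
training,5F1H,2,-75.7,kcal/mol
training,5F1H,3,-72.4,kcal/mol
training,5IGM,1,-71.1,kcal/mol
training,5IGM,2,-71.1,kcal/mol
training,5IGM,3,-71.1,kcal/mol
training,5E9V,1,-51.5,kcal/mol
training,5E9V,2,-47.7,kcal/mol
training,5E9V,3,-52.2,kcal/mol
training,6V14,1,-69.1,kcal/mol
training,6V14,2,-64.4,kcal/mol
training,6V14,3,-64.0,kcal/mol
training,4XY8,1,-43.5,kcal/mol
training,4XY8,2,-51.3,kcal/mol
training,4XY8,3,-39.3,kcal/mol
training,4Z6I,1,-54.2,kcal/mol
training,4Z6I,2,-78.5,kcal/mol
training,4Z6I,3,-76.9,kcal/mol
training,6V0S,1,-25.6,kcal/mol
training,6V0S,2,-45.6,kcal/mol
training,6V0S,3,-43.4,kcal/mol
test,9,1,-78.88,kcal/mol
test,10a,1,-52.01,kcal/mol
test,10b,1,-70.70,kcal/mol
test,11,1,-70.41,kcal/mol
test,12,1,-76.08,kcal/mol
test,13,1,-58.69,kcal/mol
test,14,1,-64.27,kcal/mol
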