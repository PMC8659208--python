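set,system,docking_score,docking_contacts,mmgbsa,site_energy,total_energy,md_contacts,rmsd_mean,rmsf_violations,rg_width,label
training,4UIW,-7.6,8,-87.80,-29.13,-62.96,5,2.17,0,0.70,Excellent
training,5F1H,-9.2,7,-74.73,-15.20,-56.43,3,2.21,0,0.47,Good
training,5IGM,-6.7,7,-71.09,-20.48,-20.48,3,2.55,0,0.63,Good
training,5E9V,-4.8,7,-50.44,1.61,-32.19,0,2.98,0,1.27,Intermediate
training,6V14,-8.3,7,-65.86,-20.57,-20.57,2,2.13,0,0.72,Intermediate
training,4XY8,-9.3,7,-44.67,0.00,0.00,1,4.05,1,1.15,Bad
training,4Z6I,-7.9,8,-69.85,-13.99,-13.99,2,2.94,2,0.66,Intermediate
training,6V0S,-4.5,7,-38.17,5.55,-12.45,1,2.74,0,0.58,Bad
test,9,-9.4,8,-78.88,-17.67,-61.60,4,2.97,0,0.69,Excellent
test,10a,-5.3,7,-52.01,-5.88,-13.00,0,3.25,0,0.90,Bad
test,10b,-3.8,6,-70.70,-17.36,-17.36,3,2.19,0,0.75,Good
test,11,-7.4,7,-70.41,-13.66,-13.66,3,3.35,0,1.00,Intermediate
test,12,-5.9,9,-76.08,-15.37,-29.07,4,3.23,1,0.86,Good
test,13,-5.7,8,-58.69,-12.03,-17.96,2,3.32,0,0.94,Bad
test,14,-7.9,8,-64.27,-18.56,-18.56,3,3.15,2,1.01,Bad
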