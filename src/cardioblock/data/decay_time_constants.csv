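# Apparent monoexponential inactivation time constants (ms) of peak Na+ current,
# measured in the same cell with the standard activation protocol before
# (tau_initial) and 3 min after (tau_treated) bath application.
# group: drug = cenobamate 200 uM in vehicle; vehicle = vehicle solution only.
# excluded: recording contaminated by an adjacent cell coupled through gap
# junctions; not used in further analysis.
exp,group,tau_initial_ms,tau_treated_ms,excluded
23314,drug,1.19,0.67,False
23317,drug,1.63,0.83,False
23321,drug,3.49,1.21,True
a3321,drug,0.87,0.56,False
23324,drug,0.67,0.58,False
a3324,drug,0.98,0.56,False
23311,vehicle,1.96,1.86,False
23325,vehicle,1.89,1.88,False
23517,vehicle,4.00,4.06,False
23519,vehicle,2.09,2.04,False
a3519,vehicle,0.78,0.79,False
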