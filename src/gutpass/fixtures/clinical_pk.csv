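# Clinical inputs for the Fa x Fg back-calculation: absolute oral
# bioavailability F, blood-to-plasma ratio RB, plasma clearance CLp
# (mL/min/kg) and renal fraction fe, for 12 marketed drugs.
# expected_match=False marks drugs whose published Fa x Fg percentage is
# not reproduced by the clearance chain from these inputs.
drug,F,RB,CLp_mL_min_kg,fe,expected_match,source_note
atenolol,0.5,0.95,2.5,1.0,True,RB measured in-house
atorvastatin,0.14,0.85,8.93,0.01,False,RB measured in-house
buspirone,0.05,0.81,28.3,0.45,True,
felodipine,0.15,0.7,11.0,0.0,True,
indinavir,0.6,0.84,18.0,0.085,True,
irinotecan,0.25,0.82,7.0,0.32,False,
midazolam,0.4,0.64,5.3,0.0,False,RB measured in-house
nifedipine,0.9,0.67,7.3,0.0,True,
oxybutynin,0.06,0.686,5.1,0.0,True,fe from prescribing information
quinidine,0.9,0.87,4.0,0.15,True,
rosuvastatin,0.2,0.75,11.0,0.3,False,RB measured in-house
saquinavir,0.04,0.74,13.0,0.01,True,fe from prescribing information
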