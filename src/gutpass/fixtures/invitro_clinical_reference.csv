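# Published comparison of in vitro intestinal availability (percent of the
# apical dose recovered in the basal compartment after 24 h) with the
# clinical Fa x Fg percentage for the same 12 drugs.
drug,invitro_recovery_pct,clinical_fafg_pct,dme_transporters
atenolol,86,50,
atorvastatin,43,61,CYP3A4/BCRP/MRP2
buspirone,60,70,CYP3A4
felodipine,47,62,CYP3A4
indinavir,53,100,CYP3A4
irinotecan,62,39,"Esterases, CYP3A4"
midazolam,47,59,CYP3A4
nifedipine,110,100,CYP3A4
oxybutynin,16,9,"Esterases, CYP3A4"
quinidine,85,100,"CYP3A4, etc."
rosuvastatin,30,62,CYP2C9/BCRP/MRP2
saquinavir,18,25,CYP3A4/P-gp
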