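# Substrate / selective-metabolite map for the DME activity screen, with
# the tested substrate concentration range per enzyme.
drug,enzyme,metabolite,internal_standard,conc_low_um,conc_high_um,solvent
Phenacetin,CYP1A2,Acetaminophen,d4-Acetaminophen,10,100,20% ACN
Bupropion,CYP2B6,2-OH-Bupropion,d8-OH-bupropion,15,300,Aqua bidest.
Amodiaquine,CYP2C8,OH-Desethyl-Amodiaquine,d5-Desethylamodiaquine,20,200,Aqua bidest.
Diclofenac,CYP2C9,4-OH-Diclofenac,(13C6)4'-OH-Diclofenac,20,200,20% ACN
S-Mephenytoin,CYP2C19,4-OH-Mephenytoin,d3-OH-Mephenytoin,20,200,40% ACN
Testosterone,CYP3A4,6b-OH-Testosterone,d3-6b-OH-Testosterone,40,400,ACN/MeOH
Midazolam,CYP3A4,1-OH-Midazolam,d4-1-OH-Midazolam,5,100,Ready-to-use solution
Dextromethorphan,CYP2D6,Dextrorphan,d3-Dextrorphan,10,100,Aqua bidest.
7-OH-Coumarin,UGT,7-OH-Coumarin-Glucuronid,a-Naphtylglucuronid,15,150,40% ACN
7-OH-Coumarin,SULT,7-OH-Coumarin-Sulfat,a-Naphtylglucuronid,15,150,40% ACN
b-Estradiol,UGT1A1,b-Estradiol-3-Glucuronid,a-Naphtylglucuronid,20,200,DMSO
Astemizol,CYP2J2,O-Desmethyl-Astemizol,Dextrorphan tartrate,2,50,30% ACN + 10 mM HCl
BIBF1120,CES,BIBF1202,d8-BIBF1202,10,100,ACN/MeOH
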