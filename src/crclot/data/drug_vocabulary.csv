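drug_id,canonical_name,drug_class,is_biologic,default_cycle_days
fluorouracil,5-fluorouracil,fluoropyrimidine_iv,False,14
capecitabine,Capecitabine,fluoropyrimidine_oral,False,28
s1,Tegafur/gimeracil/oteracil (S-1),fluoropyrimidine_oral,False,21
uft,Uracil/tegafur (UFT),fluoropyrimidine_oral,False,28
oxaliplatin,Oxaliplatin,oxaliplatin,False,14
irinotecan,Irinotecan,irinotecan,False,14
trifluridine_tipiracil,Trifluridine/tipiracil (FTD/TPI),ftd_tpi,False,21
bevacizumab,Bevacizumab,antiangiogenic,True,14
ramucirumab,Ramucirumab,antiangiogenic,True,14
aflibercept_beta,Aflibercept beta,antiangiogenic,True,14
cetuximab,Cetuximab,anti_egfr,True,14
panitumumab,Panitumumab,anti_egfr,True,14
pembrolizumab,Pembrolizumab,other_targeted,False,21
regorafenib,Regorafenib,other_targeted,False,28
sorafenib,Sorafenib,other_targeted,False,28
leucovorin,Leucovorin (folinic acid),leucovorin,False,14
amlodipine,Amlodipine,antihypertensive,False,28
candesartan,Candesartan,antihypertensive,False,28
butylscopolamine,Butylscopolamine,anticholinergic,False,28
warfarin,Warfarin,anticoagulant,False,28
edoxaban,Edoxaban,anticoagulant,False,28
acetaminophen,Acetaminophen,other,False,28
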