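name,family,r1,r2,r3,r4,n_oh
cyanidin,anthocyanidin,OH,H,OH,OH,5
delphinidin,anthocyanidin,OH,OH,OH,OH,6
malvidin,anthocyanidin,OCH3,OCH3,OH,OH,4
pelargonidin,anthocyanidin,H,H,OH,OH,4
peonidin,anthocyanidin,OCH3,H,OH,OH,4
cyanidin-3-coumaroyl-sambubioside-5-galactoside,anthocyanin,OH,H,coumaroyl-sam,gal,3
cyanidin-3-sambubioside-5-galactoside,anthocyanin,OH,H,sam,gal,3
cyanidin-3-arabinoside,anthocyanin,OH,H,ara,OH,4
cyanidin-3-galactoside,anthocyanin,OH,H,gal,OH,4
cyanidin-3-glucoside,anthocyanin,OH,H,glc,OH,4
cyanidin-3-rutinoside,anthocyanin,OH,H,rut,OH,4
"cyanidin-3,5-diglucoside",anthocyanin,OH,H,glc,glc,3
delphinidin-3-glucoside,anthocyanin,OH,OH,glc,OH,5
delphinidin-3-rutinoside,anthocyanin,OH,OH,rut,OH,5
malvidin-3-galactoside,anthocyanin,OCH3,OCH3,gal,OH,3
malvidin-3-glucoside,anthocyanin,OCH3,OCH3,glc,OH,3
"malvidin-3,5-diglucoside",anthocyanin,OCH3,OCH3,glc,glc,2
pelargonidin-3-glucoside,anthocyanin,H,H,glc,OH,3
peonidin-3-galactoside,anthocyanin,OCH3,H,gal,OH,3
peonidin-3-glucoside,anthocyanin,OCH3,H,glc,OH,3
petunidin-3-glucoside,anthocyanin,OH,OCH3,glc,OH,4
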