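compound,experimental,pm6,pm7
cyanidin,33,35.3,33.2
delphinidin,42,42.6,41.0
malvidin,24,26.6,26.1
pelargonidin,31,28.3,27.6
peonidin,33,31.4,29.3
cyanidin-3-coumaroyl-sambubioside-5-galactoside,26,22.4,25.2
"cyanidin-3,5-diglucoside",21,22.6,20.9
cyanidin-3-arabinoside,26,28.5,27.3
cyanidin-3-sambubioside-5-galactoside,22,22.1,21.5
cyanidin-3-galactoside,25,30.3,30.2
cyanidin-3-glucoside,32,31.1,28.8
cyanidin-3-rutinoside,25,27.0,27.5
delphinidin-3-glucoside,42,35.4,38.1
delphinidin-3-rutinoside,32,33.4,30.4
"malvidin-3,5-diglucoside",14,16.6,14.9
malvidin-3-galactoside,22,22.9,21.3
malvidin-3-glucoside,26,22.6,21.2
pelargonidin-3-glucoside,20,21.0,21.2
peonidin-3-galactoside,20,22.2,21.1
peonidin-3-glucoside,26,23.6,23.5
petunidin-3-glucoside,23,28.0,25.7
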