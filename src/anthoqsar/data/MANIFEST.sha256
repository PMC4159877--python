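0d9b1fd9bbaa3cfb1e75d407764e9832b99d4d078dbe1081a2d06df11f2b62a1  table4_registry.csv
16b93b1d240ca92f0cc22d27ee0176617336f744e43af542d17bb1d6eb332009  table3_activities.csv
6800367e518265bfec318b5a14710be22dd917dffb2eadded7ed720bc5ce3a01  table2_bde.csv
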