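revision,pattern,category
10,C00-D48,cancers
10,I00-I99,cardiovascular
10,J00-J22,respiratory_infections
10,U04,respiratory_infections
10,J30-J99,chronic_respiratory
10,F10-F19,substance_use
10,O00-O99,maternal
10,P00-P96,perinatal
10,V01-X59,injuries_unintentional
10,Y40-Y89,injuries_unintentional
10,X60-Y09,injuries_intentional
10,Y35-Y36,injuries_intentional
10,A00-Z99,other
9,140-239,cancers
9,390-459,cardiovascular
9,460-466,respiratory_infections
9,480-488,respiratory_infections
9,490-519,chronic_respiratory
9,291-292,substance_use
9,303-305,substance_use
9,630-679,maternal
9,760-779,perinatal
9,E800-E949,injuries_unintentional
9,E950-E979,injuries_intentional
9,001-999,other
9,E000-E999,other
9,V01-V99,other
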