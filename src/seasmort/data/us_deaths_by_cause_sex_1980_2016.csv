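category,male,female
cancers,10481582,9476530
cardiovascular,16238344,17210556
chronic_respiratory,2791652,2595950
respiratory_infections,1138053,1303019
injuries_unintentional,2489142,1348187
injuries_intentional,1545734,419983
other,8873696,9941748
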