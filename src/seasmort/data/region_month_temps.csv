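region,month,temp_c
southeast,2,9.3
northeast,2,-3.8
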