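region,population_2016,mean_annual_temp_c
central,50191326,11.6
east_north_central,24418738,8.0
northeast,64046741,10.6
northwest,13811810,8.2
south,45388414,18.0
southeast,59356072,18.4
southwest,17613981,13.6
west,43708574,16.6
west_north_central,5168753,7.6
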