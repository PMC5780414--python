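station_id,lat,lon,bottom_depth_m,sub_basin
ST1,34.9997,-8.3328,2735,Atlantic
ST2,36.5161,-1.0006,2640,Alboran Sea
ST3,39.3217,6.0797,2853,Catalan Balearic
ST4,39.4992,12.9992,3571,Tyrrhenian Sea
ST5,36.4928,15.6594,3675,Ionian Sea
ST6,35.3053,21.3892,3625,Ionian Sea
ST7,33.9950,26.0383,4346,Levantine
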