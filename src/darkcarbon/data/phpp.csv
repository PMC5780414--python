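station_id,sub_basin,phpp_insitu,phpp_insitu_sd,phpp_model,phpp_model_sd,abd_integral_published,abd_integral_sd_published
ST2,Alboran Sea,448,188,545,321,465,71
ST3,Catalan Balearic,533,367,509,199,645,48
ST4,Tyrrhenian Sea,367,83,279,118,396,49
ST5,Ionian Sea,324,126,189,99,873,99
ST6,Ionian Sea,324,126,189,99,864,89
ST7,Levantine,149,80,208,110,632,61
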