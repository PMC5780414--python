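station_id,depth_m,temp_c,salinity,dic_mmol_l,pa_cells_ml,pa_sd,php,php_sd,pr,pr_sd,abd,abd_sd,flags
ST1,200,14.13,36.01,,240000,21000,19.4,0.8,967,51,394,39,
ST1,750,11.69,36.06,,180000,8000,11.0,0.4,987,45,347,27,
ST1,2000,4.58,35.17,,92000,8000,7.7,0.0,377,19,0.40,0.01,
ST1,2728,3.10,34.97,,75000,7000,5.5,0.0,204,8,4.4,0.4,
ST2,200,13.18,38.41,,450000,42000,34.6,1.1,1079,54,268,33,
ST2,400,13.24,38.53,,350000,27000,,,794,35,198,24,
ST2,1500,13.08,38.47,,260000,19000,12.5,0.3,763,39,204,26,
ST2,2633,13.27,38.48,,170000,14000,38.9,0.7,733,22,142,16,
ST3,200,13.52,38.30,,460000,24000,28.6,0.6,763,28,250,20,
ST3,400,13.56,38.60,,150000,9000,8.2,0.6,946,46,210,11,
ST3,1500,13.08,38.47,,220000,11000,13.7,0.1,631,31,240,14,
ST3,2837,13.31,38.49,,180000,8000,97.4,1.9,651,17,281,18,
ST4,200,14.04,38.64,,187000,19000,5.5,0.1,1577,99,114,14,
ST4,400,14.05,38.74,,131000,9000,3.8,0.1,366,13,231,21,
ST4,2500,13.43,38.52,,99000,7000,5.5,0.1,753,37,59,9,
ST4,3500,13.56,38.50,,48000,4000,27.8,0.5,926,39,48,6,
ST5,200,14.81,38.94,,170000,13000,23.0,0.2,794,41,411,31,
ST5,400,14.13,38.84,,132000,11000,7.0,0.1,662,34,215,27,
ST5,1500,13.79,38.75,,122000,11000,5.5,0.1,662,17,200,11,
ST5,2000,13.80,38.74,,72000,6000,64.6,2.8,550,21,249,16,
ST5,3000,13.91,38.74,,84000,6000,44.4,1.9,672,17,312,31,
ST5,3655,13.94,38.74,,79000,9000,37.0,3.0,712,26,248,21,
ST6,200,14.77,38.92,,221000,17000,12.7,0.7,1761,75,140,16,
ST6,500,14.13,38.85,,140000,8000,13.0,0.5,662,16,370,36,
ST6,1000,13.74,38.75,,150000,12000,4.8,0.1,641,32,290,20,
ST6,2000,13.84,38.75,,75000,5000,8.9,0.2,539,19,245,14,
ST6,3000,13.94,38.74,,53000,3000,6.7,0.1,570,13,207,19,
ST6,3400,13.94,38.74,,1005000,65000,,,,,730,41,DHAL-influenced
ST7,200,17.80,39.17,,423000,34000,89.0,4.1,1333,69,160,21,
ST7,750,14.36,38.89,,218000,13000,33.1,0.8,814,42,133,14,
ST7,1500,13.88,38.77,,205000,8000,34.3,0.9,1048,41,207,16,
ST7,2000,13.85,38.76,,127000,9000,81.8,4.1,590,18,126,10,
ST7,3000,14.08,38.77,,136000,16000,125.3,4.5,662,16,143,6,
ST7,4000,14.20,38.76,,84000,8000,97.7,7.4,773,35,163,11,
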