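station_id,depth_m,cspcd,cspcd_sd,csabd,csabd_sd
ST1,200,4.11,0.57,1.64,0.39
ST1,750,5.54,0.49,1.93,0.24
ST1,2000,4.18,0.57,0.004,0.001
ST1,2728,2.79,0.36,0.06,0.01
ST2,200,2.47,0.35,0.60,0.13
ST2,400,,,0.57,0.12
ST2,1500,2.98,0.37,0.78,0.16
ST2,2633,4.54,0.35,0.84,0.16
ST3,200,1.72,0.15,0.54,0.07
ST3,400,6.36,0.69,1.40,0.16
ST3,1500,2.93,0.29,1.09,0.11
ST3,2837,4.16,0.29,1.56,0.17
ST4,200,8.46,1.39,0.61,0.14
ST4,400,2.82,0.29,1.76,0.28
ST4,2500,7.66,0.91,0.60,0.13
ST4,3500,19.87,2.48,1.00,0.21
ST5,200,4.81,0.60,2.42,0.37
ST5,400,5.07,0.68,1.63,0.34
ST5,1500,5.47,0.63,1.64,0.24
ST5,2000,8.54,1.04,3.46,0.51
ST5,3000,8.53,0.83,3.71,0.63
ST5,3655,9.48,1.44,3.14,0.62
ST6,200,8.03,0.96,0.63,0.12
ST6,500,4.82,0.39,2.64,0.41
ST6,1000,4.31,0.56,1.93,0.29
ST6,2000,7.31,0.74,3.27,0.40
ST6,3000,10.88,0.86,3.91,0.57
ST6,3400,,,0.73,0.09
ST7,200,3.36,0.44,0.38,0.08
ST7,750,3.89,0.42,0.61,0.1
ST7,1500,5.28,0.41,1.01,0.12
ST7,2000,5.29,0.54,0.99,0.15
ST7,3000,5.79,0.83,1.05,0.17
ST7,4000,10.37,1.50,1.94,0.31
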