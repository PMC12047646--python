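material,density_g_cm3
air,0.001205
water,1.000
adipose,0.930
fibroglandular,1.040
skin,1.090
calcification,3.060
aluminum,2.699
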