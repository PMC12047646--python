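material,element,weight_fraction
air,C,0.000124
air,N,0.755268
air,O,0.231781
air,Ar,0.012827
water,H,0.111894
water,O,0.888106
adipose,H,0.112000
adipose,C,0.619000
adipose,N,0.017000
adipose,O,0.252000
fibroglandular,H,0.102000
fibroglandular,C,0.184000
fibroglandular,N,0.032000
fibroglandular,O,0.677000
fibroglandular,P,0.005000
skin,H,0.100000
skin,C,0.204000
skin,N,0.042000
skin,O,0.645000
skin,Na,0.002000
skin,P,0.001000
skin,S,0.002000
skin,Cl,0.003000
skin,K,0.001000
calcification,Ca,0.399000
calcification,P,0.185000
calcification,O,0.414000
calcification,H,0.002000
aluminum,Al,1.000000
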