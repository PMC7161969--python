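label,r,g,b,ph,density
yellow,0.40,0.41,0.19,4.0,0.40
red,0.70,0.17,0.13,5.6,0.55
orange,0.57,0.26,0.17,6.7,0.70
blue,0.06,0.36,0.58,8.5,1.35
green,0.16,0.56,0.28,9.3,1.75
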