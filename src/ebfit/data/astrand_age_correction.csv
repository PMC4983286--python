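# Classical age-correction factors for the Astrand nomogram.
age,factor
15,1.1
25,1.0
35,0.87
40,0.83
45,0.78
50,0.75
55,0.71
60,0.68
65,0.65
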