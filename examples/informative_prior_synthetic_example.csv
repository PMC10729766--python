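combination,probability
DDLW,0.55
HHLW,0.20
LLWW,0.05
DDLL,0.04
LLLL,0.03
LLLW,0.02
HHLL,0.02
unknown,0.09
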