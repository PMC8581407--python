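set_name	score_name	step	direction
IC_CORE	IC	sensing	core
CASP1_UP	CASP1	activation	up_regulated
CASP1_DN	CASP1	activation	down_regulated
GSDMD_UP	GSDMD	termination	up_regulated
GSDMD_DN	GSDMD	termination	down_regulated
IL1B_UP	IL1B	termination	up_regulated
IL1B_DN	IL1B	termination	down_regulated
IL18_UP	IL18	termination	up_regulated
IL18_DN	IL18	termination	down_regulated
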