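parameter	rat_direction	human_direction	ns_aligned_override
L-sized LDL conc.	Reduced	ns	1
L-sized LDL FC	Reduced	Reduced	0
L-sized LDL AB	Reduced	---	0
M-sized HDL PL	Reduced	Reduced	0
M-sized HDL A1	Reduced	---	0
Isoleucine	Increased	Increased	0
Formate	Reduced	---	0
LPC	Reduced	Reduced	0
PC	Reduced	Reduced	0
PG	Reduced	Reduced	0
PI	Reduced	Increased	0
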