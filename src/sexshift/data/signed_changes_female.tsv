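parameter	rat_direction	human_direction	ns_aligned_override
Tyrosine	Increased	Increased	0
Phenylalanine	Increased	Increased	0
Alanine	Increased	Increased	0
Glucose	Reduced	Increased	0
Lactate	Increased	Increased	0
Acetate	Reduced	Reduced	0
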