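# Morphological panel of tumor cell lines: literature-reported mean
# diameter and effective Young's modulus (stiffness) used for
# operating-pressure curves.
name,diameter_um,stiffness_pa
A549,17,430
MCF-7,20,360
PC3-9,18,130
HeLa,15,387
MDA-MB-231,15.5,206
SW480,11,580
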