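# Measured fraction of single A549 cells captured per gap array at
# 10 uL/min (normalized counts over two chips).
gap_um,captured_fraction
>14,0.05
10,0.13
8,0.23
4,0.59
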