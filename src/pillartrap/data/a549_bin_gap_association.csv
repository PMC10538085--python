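# Observed association between A549 diameter bins and the gap array where
# cells of that bin were predominantly captured, with the measured share of
# the population per bin.  Shipped as an empirical fixture: no single
# size-fraction threshold reproduces it (the 25% rule holds for the smaller
# cells only).  Shares are as printed (they total 101%) and are renormalized
# by consumers.  gap_um ">14" denotes the coarse inlet filter array.
diameter_lo_um,diameter_hi_um,population_share,gap_um
12,18,0.60,4
18,20,0.23,8
20,23,0.13,10
23,28,0.05,>14
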