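adsorbent,d10_um,d50_um,d90_um,volume_weighted_mean_um
CG300m,60,82,112,84
CG161c,86,117,158,120
HAC,363,492,656,504
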