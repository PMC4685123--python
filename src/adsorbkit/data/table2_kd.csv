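adsorbent,molecular_mass,kd
CG161c,92,1.00
CG161c,570,0.82
CG161c,1920,0.67
CG161c,3460,0.59
CG161c,9630,0.41
CG161c,17300,0.29
CG161c,27500,0.15
CG161c,62300,0.02
CG161c,96000,0.00
CG161c,139000,0.00
CG161c,319000,0.00
CG161c,524000,0.00
CG161c,925000,0.00
CG300m,92,1.00
CG300m,570,0.85
CG300m,1920,0.76
CG300m,3460,0.70
CG300m,9630,0.60
CG300m,17300,0.53
CG300m,27500,0.44
CG300m,62300,0.26
CG300m,96000,0.13
CG300m,139000,0.07
CG300m,319000,0.01
CG300m,524000,0.00
CG300m,925000,0.00
HAC,92,1.00
HAC,570,0.56
HAC,1920,0.29
HAC,3460,0.21
HAC,9630,0.11
HAC,17300,0.10
HAC,27500,0.08
HAC,62300,0.04
HAC,96000,0.03
HAC,139000,0.02
HAC,319000,0.01
HAC,524000,0.00
HAC,925000,0.00
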