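probe,molecular_mass,stokes_radius_nm
toluene,92,0.18
polystyrene,570,0.51
polystyrene,1920,1.05
polystyrene,3460,1.48
polystyrene,9630,2.71
polystyrene,17300,3.82
polystyrene,27500,5.01
polystyrene,62300,8.11
polystyrene,96000,10.46
polystyrene,139000,13.00
polystyrene,319000,21.19
polystyrene,524000,28.37
polystyrene,925000,39.63
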