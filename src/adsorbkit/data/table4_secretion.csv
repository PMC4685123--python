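condition,il8_pg_ml,il8_sd,il6_pg_ml,il6_sd
cell_plasma_control,326,15,231,187
positive_control,6249,858,4056,2124
CG300m,657,72,141,23
HAC,600,53,143,14
CG161c,130,15,66,6
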