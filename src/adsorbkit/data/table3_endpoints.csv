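analyte,condition,time_h,concentration_pg_ml,sd_pg_ml
TNF-alpha,control,6,3102,533
TNF-alpha,CG161c,6,177,7
TNF-alpha,CG300m,6,1131,16
TNF-alpha,HAC,6,1445,212
IL-1beta,control,6,830,190
IL-1beta,CG161c,6,7,1
IL-1beta,CG300m,6,10,1
IL-1beta,HAC,6,45,3
IL-6,control,6,24273,13446
IL-6,CG161c,6,59,18
IL-6,CG300m,6,65,3
IL-6,HAC,6,2587,1254
IL-8,control,6,4837,2300
IL-8,CG161c,6,8,7
IL-8,CG300m,6,10,6
IL-8,HAC,6,60,52
IL-10,control,6,51,9
IL-10,CG161c,6,<2,
IL-10,CG300m,6,<2,
IL-10,HAC,6,7,4
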