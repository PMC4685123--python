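adsorbent,vt_ml,v0_ml,vb_printed_ml,vp_printed_ml,porosity_printed_percent,pore_radius_lower_printed_nm,pore_radius_upper_printed_nm,manufacturer_pore_radius_nm
CG161c,2.30,1.06,1.792,1.23,86.2,5.0,8.1,7.5
CG300m,2.25,1.14,1.792,1.11,82.3,10.3,13.0,15
HAC,2.31,1.13,1.792,1.18,86.6,3.8,5.0,2.5
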