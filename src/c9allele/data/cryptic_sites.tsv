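site	chrom	pos	offset_bp
C1	chr9	27572766	665
C2	chr9	27572520	910
C3	chr9	27571136	2295
C4	chr9	27571123	2308
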