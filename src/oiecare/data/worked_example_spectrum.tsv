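mz	abundance
1141.613770	128926.921875
1142.617676	480992.312500
1142.910522	120854.796875
1143.120117	281777.062500
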