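ion	theo_mz	theo_rel
y10-1+	1141.607714	63.64
y10-1+	1142.610419	23.01
y20-2+	1142.611961	100.00
y20-2+	1143.113357	67.65
y72-7+	1142.607764	55.06
y72-7+	1142.894250	100.00
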