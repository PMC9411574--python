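SLC3A2	amino-acid transporter heavy chain
SLC7A1	cationic amino-acid transporter
SLC18B1	vesicular polyamine transporter
SLC22A18	organic cation transporter
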