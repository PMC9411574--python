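# Illustrative ubiquitin-proteasome panel for demos; not a curated set.
UBB	ubiquitin B
UBC	ubiquitin C
UBA52	ubiquitin-ribosomal fusion
PSMB5	proteasome subunit beta 5
PSMA1	proteasome subunit alpha 1
UBE2L3	E2 conjugating enzyme
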