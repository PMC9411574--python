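TYR	tyrosinase
TYRP1	tyrosinase-related protein 1 (TRP-1)
DCT	dopachrome tautomerase (TRP-2)
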