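name,ratio,provenance
VPDB,0.01118,"Vienna Peedee Belemnite 13C/12C, anchored to NBS-19 (+1.95 permil) and L-SVEC (-46.6 permil)"
33S-reference,0.0078791,33S/32S of the IAEA-S-1 reference material
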