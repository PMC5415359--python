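# Transmembrane helix residue spans (author numbering, inclusive) used
# for the M1-M4 Cα RMSD selection.  These are versioned package
# defaults: approximate helix assignments for the channels analysed
# plus the spans of the synthetic channel model; override with a user
# file for other constructs.

[TREK2]
M1 = [72, 103]
M2 = [184, 215]
M3 = [221, 252]
M4 = [302, 333]

[TWIK1]
M1 = [25, 56]
M2 = [146, 177]
M3 = [183, 214]
M4 = [254, 285]

[SYNTHETIC]
M1 = [70, 100]
M2 = [190, 215]
M3 = [218, 248]
M4 = [300, 335]
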