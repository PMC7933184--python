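# Example binding-mode footprints for the CD44 hyaluronan-binding domain (residues 20-169).
# These are binary residue MEMBERSHIP lists assembled from the residue sets named in the
# accompanying analyses (upright patch; crystallographic-groove arginines R41/R78; flanking
# arginines R150/R154/R162), NOT the original per-residue ligand-contact weights, which are
# an external input. Weights are 1.0 for membership.
mode	residue_id	weight
crystallographic	41	1.0
crystallographic	78	1.0
parallel	41	1.0
parallel	150	1.0
parallel	154	1.0
upright	38	1.0
upright	43	1.0
upright	44	1.0
upright	79	1.0
upright	80	1.0
upright	105	1.0
upright	113	1.0
upright	114	1.0
upright	162	1.0
upright	166	1.0
key_arginines	41	1.0
key_arginines	78	1.0
key_arginines	150	1.0
key_arginines	154	1.0
key_arginines	162	1.0
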