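# 5S rRNA structural descriptor, Thermoanaerobacterales screen.
# Three conserved core fragments (core residues 3-11, 72-80, 109-117)
# separated by bounded variable-length spacers; the 5' terminal 8-mer must
# pair antiparallel with the 3' terminal fragment (helix I; G:U allowed,
# the archetype itself carries a G:U at this position).
YYYGGYGRY
N[50:180]
GAUGRUASU
N[20:150]
YYGCCRRR
pair(block1[0:8], block5[0:8], wobble=yes)
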