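# 5S rRNA structural descriptor, Halobacteria screen.
# GGCGGC within the 5' fragment pairs antiparallel with GCCGCC within the
# 3' fragment (helix I).
MGGCGGCC
N[50:180]
BNNMSUACU
N[20:150]
TCGCCGCC
pair(block1[1:7], block5[2:8], wobble=yes)
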