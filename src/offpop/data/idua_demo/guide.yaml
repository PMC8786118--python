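# sgRNA targeting the IDUA W402X locus (chr4:996530-996552, hg19)
name: idua_w402x
spacer: GCTCTAGGCCGAAGTGTCGC
pam_pattern: NGG
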