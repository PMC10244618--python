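# NF2 isoform architectures (1-based, closed intervals, isoform-1 reference).
# Isoform 7 skips exons 2-3 (residues 39-121) and ends in an exon-16-derived
# C-terminus that begins at isoform-1 residue 580 and is 5 residues shorter.
reference_length: 595
isoforms:
  NF2-iso1:
    deletion: null
    cterm_divergence_start: null
    cterm_delta: 0
  NF2-iso7:
    deletion: [39, 121]
    cterm_divergence_start: 580
    cterm_delta: -5
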