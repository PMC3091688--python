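acceptor_dinucleotide: AG
alpha_protein_length: 143
beta_protein_lengths:
- 147
- 148
donor_dinucleotide: GT
exon_length_slack: 2
nonbohr_cterm_residue: F
nonbohr_position: 93
nonbohr_position_includes_met: true
nonbohr_position_residue: A
nonbohr_protein_length: 147
required_exon_count: 3
required_intron_count: 2
subunit_of_variant:
  alpha: alpha
  beta: beta
  beta_nonbohr: beta
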