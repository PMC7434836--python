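# Seven-feature low-dimensional anticancer-peptide model.
# One feature name per line; resolvable by acpkit.encoders.resolve_feature.
GL.gap4
hydrophobicity_PRAM900101.Tr2332
polarizability.2.residue0
Pc1.C
Xc1.K
Pc2.Hydrophobicity.8
secondarystruct.1.residue0
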