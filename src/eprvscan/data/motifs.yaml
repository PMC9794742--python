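# Position-constrained surrogate motifs for the six Caulimoviridae protein
# domains tracked by the architecture annotator. Patterns are simplified
# consensus expressions (not profile HMMs); each motif's consensus embeds
# the canonical catalytic/structural residues of the domain it stands for
# (e.g. the CCHC zinc knuckle, the retropepsin D-T/S-G triad, the YxDD
# polymerase box).
motifs:
  - name: zinc_finger
    pattern: C-x(2)-C-x(4)-H-x(4)-C
    consensus: CQKCNAGKHLAREC
    min_score: 4
  - name: movement_protein
    pattern: G-[DE]-x(2)-L-P-L-x-G
    consensus: GDKVLPLTG
    min_score: 6
  - name: aspartic_proteinase_1
    pattern: "[LIVM]-x-D-T-G-[SA]-x(2)-[LIVM]"
    consensus: LVDTGSEVI
    min_score: 6
  - name: aspartic_proteinase_2
    pattern: "[LIVMF]-x-D-S-G-[SAC]-x-[DE]"
    consensus: FTDSGCSD
    min_score: 6
  - name: reverse_transcriptase
    pattern: "[YF]-x-D-D-[ILMV]-[ILMV]-x(2)-[GSA]"
    consensus: YVDDILGKA
    min_score: 6
  - name: rnaseh
    pattern: "[ILV]-[DE]-[ST]-D-[AG]-x(2)-[YWF]"
    consensus: IDSDAKEY
    min_score: 6
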