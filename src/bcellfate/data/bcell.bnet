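# B-cell terminal differentiation regulatory network (22 nodes).
# BoolNet-style rules; "&" = AND, "|" = OR, "!" = NOT.
# Input (environment) nodes are declared with factor 0: they decay to the
# inactive state unless clamped. ASCII node names: NFkB = NF-kB, IL2 = IL-2,
# IL4 = IL-4, IL21 = IL-21 (receptors IL2R, IL4R, IL21R likewise).
targets, factors
AID, (STAT6 | (NFkB & Pax5)) & !Blimp1
Ag, 0
Bach2, Pax5 & !Blimp1
Bcl6, (STAT5 | STAT6 | (Pax5 & Bcl6)) & !(Blimp1 | Irf4 | ERK)
BCR, Ag
Blimp1, (ERK | STAT3) | (Irf4 & !(Pax5 | Bcl6 | Bach2))
CD40, CD40L
CD40L, 0
ERK, BCR
IL2, 0
IL21, 0
IL21R, IL21
IL2R, IL2
IL4, 0
IL4R, IL4
Irf4, (NFkB | Irf4) | (Blimp1 & !Bcl6)
NFkB, CD40
Pax5, (Pax5 | !Irf4) & !(Blimp1 | ERK)
STAT3, IL21R
STAT5, IL2R
STAT6, IL4R
XBP1, Blimp1 & !Pax5
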