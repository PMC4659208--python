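# Synthetic nominal circle-of-Willis dimension table (NOT patient data).
# Left-right symmetric, literature-plausible values: afferent/efferent
# vessel classes follow standard 1D cerebral-arterial network models
# (Alastruey et al. 2007, J Biomech 40:1794-1805); the communicating
# arteries use the classical lumped-model values (PCoA 1.0 mm, ACoA
# 1.2 mm, Hillen-type models), which reproduce the expected baseline
# pattern of a symmetric circle: zero ACoA cross-flow and only a small
# anterior-to-posterior PCoA flow.
id,length_mm,diameter_mm
RICA,177.0,4.00
LICA,177.0,4.00
RVA,148.0,2.72
LVA,148.0,2.72
BA,29.0,3.24
RA1,12.0,2.34
LA1,12.0,2.34
ACoA,3.0,1.20
RP1,5.0,2.14
LP1,5.0,2.14
RPCoA,15.0,1.00
LPCoA,15.0,1.00
RMCA,119.0,2.86
LMCA,119.0,2.86
RA2,103.0,2.40
LA2,103.0,2.40
RP2,86.0,2.10
LP2,86.0,2.10
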