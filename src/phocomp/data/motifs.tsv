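# Curated promoter-element fixture (synthetic): literature consensus strings
# for common plant cis-regulatory element classes; not a database export.
# Columns: name, type (pwm|iupac), model, threshold.
# pwm models given as a consensus are expanded to a sharp matrix
# (0.91 on the consensus base) and scored as log2-odds vs uniform background.
name	type	model	threshold
ABRE	pwm	ACGTGGC	5
MBS	pwm	CAACTG	5
G-box-light	pwm	CACGTG	5
GCN4-endosperm	pwm	TGAGTCA	5
TATA-box	iupac	TATAWA	5
CAAT-box	iupac	CCAAT	4
Box4-light	iupac	ATTAAT	5
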