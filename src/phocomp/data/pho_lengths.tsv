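# Published per-species sequence lengths and percent identity to the
# O. sativa reference for the plastidial (PHO1) and cytosolic (PHO2)
# starch phosphorylase families.  Percent columns are identity vs the
# reference; accession is the printed protein record id.
species	family	clade	cdna_bp	cdna_pct	cds_bp	cds_pct	gene_bp	gene_pct	protein_aa	protein_pct	accession
S. bicolor	PHO1	monocot	3445	79.0	2958	91.9	6536	62.6	985	86.2	XP_021306483.1
Z. mays	PHO1	monocot	3523	78.1	2955	91.9	9022	49.2	984	85.8	NP_001296783.1
S. italica	PHO1	monocot	3385	80.9	2943	92.4	6909	62.8	980	87.2	XP_004981704.1
P. hallii	PHO1	monocot	3351	80.7	2964	91.9	6671	63.0	987	85.8	XP_025795811.1
B. distachyon	PHO1	monocot	3410	81.7	2937	92.5	7498	62.9	978	87.5	XP_003559211.1
T. aestivum	PHO1	monocot	3312	80.0	2917	90.4	7461	58.4	971	84.3	ACC59201.1
O. sativa	PHO1	monocot	3408	100	2937	100	7239	100	978	100	XP_015631420.1
H. vulgare	PHO1	monocot	3305	77.3	2907	90.6	7441	61.1	968	84.9	KAE8783983.1
A. thaliana	PHO1	dicot	3180	64.5	2889	81.5	5008	45.9	962	69.3	Q9LIB2.1
S. lycopersicum	PHO1	dicot	3332	65.0	2901	80.9	8718	46.3	966	67.0	NP_001362574.1
S. tuberosum	PHO1	dicot	4942	42.2	2901	81.6	4942	42.2	966	67.4	NP_001275215.1
C. annuum	PHO1	dicot	3456	63.2	2937	80.5	8233	45.9	978	68.5	XP_016569840.1
S. bicolor	PHO2	monocot	3167	80.8	2517	92.5	6227	60.6	838	89.5	XP_002458773.1
Z. mays	PHO2	monocot	2868	80.4	2517	92.6	12006	36.7	838	89.9	NP_001151625.1
S. italica	PHO2	monocot	2937	81.7	2514	92.4	6312	61.6	837	89.2	XP_004970602.1
P. hallii	PHO2	monocot	2979	81.2	2664	86.0	5902	59.4	897	83.2	XP_025814328.1
B. distachyon	PHO2	monocot	2909	82.5	2502	93.4	6891	62.4	833	90.3	XP_003564622.1
T. aestivum	PHO2	monocot	2856	80.4	2499	93.2	6114	62.2	832	90.3	Q9LKJ3.1
O. sativa	PHO2	monocot	3036	100	2526	100	6275	100	841	100	XP_015621275.1
H. vulgare	PHO2	monocot	2857	79.4	2499	93.5	5569	59.6	832	90.4	KAE8796869.1
A. thaliana	PHO2	dicot	3168	62.9	2526	85.1	5240	47.6	841	77.6	CAB61943.1
S. lycopersicum	PHO2	dicot	2908	65.4	2514	84.9	15109	23.7	837	77.1	XP_004246972.1
S. tuberosum	PHO2	dicot	2833	65.9	2517	85.1	13343	29.7	838	77.8	NP_001275118.1
C. annuum	PHO2	dicot	2965	65.0	2544	82.8	34548	11.8	847	75.0	XP_016542003.1
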