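neighbor_id	layer	annotation	rho
Solyc06g053710.3	transcript	ethylene receptor homolog (ETR4)	−0.971428571
Solyc09g091270.3	transcript	cotton fiber protein	−0.964285714
Solyc01g105010.3	transcript	Non-specific lipid-transfer protein-like protein	−0.960714286
Solyc02g087740.3	transcript	Plant cysteine oxidase 2	−0.957142857
Solyc07g018070.4	transcript	Double Clp-N motif-containing P-loop nucleoside triphosphate hydrolases superfamily protein	−0.957142857
Solyc03g119390.4	transcript	bHLH transcription factor 026	−0.95
Solyc01g106380.2	transcript	hypothetical protein	0.95
Solyc01g110270.3	transcript	RNA-binding CRS1 / YhbY (CRM) domain protein	0.95
Solyc03g082560.3	transcript	Aldo-keto reductase/ oxidoreductase	0.95
Solyc12g094630.2	transcript	Low-density receptor-like protein	0.95
Solyc01g105340.4	transcript	Chaperone protein DnaJ	0.953571429
Solyc02g071190.4	transcript	Carboxyl-terminal-processing protease-like protein	0.953571429
Solyc03g026200.4	transcript	protein COFACTOR ASSEMBLY OF COMPLEX C SUBUNIT B CCB2, chloroplastic	0.953571429
Solyc03g044470.4	transcript	red chlorophyll catabolite reductase	0.953571429
Solyc03g062710.4	transcript	protein NDH-DEPENDENT CYCLIC ELECTRON FLOW 5	0.953571429
Solyc12g096100.2	transcript	Protein PAM68, chloroplastic	0.953571429
A0A3Q7HR44	protein	NA	0.953571429
Solyc00g500066.1	transcript	Photosystem I assembly protein Ycf4	0.957142857
Solyc03g063240.3	transcript	Pyridoxamine 5'-phosphate oxidase-related FMN-binding protein	0.957142857
Solyc03g124060.3	transcript	Polyketide cyclase/dehydrase and lipid transport superfamily protein	0.957142857
Solyc08g075100.4	transcript	Initiation factor 4 F subunit (DUF1350)	0.957142857
Solyc11g007130.2	transcript	Major facilitator superfamily	0.957142857
A0A3Q7H1X6	protein	NA	0.967432647
Solyc07g064100.1	transcript	Chlororespiratory reduction 41	0.967857143
Solyc12g009440.2	transcript	DnaJ/Hsp40 cysteine-rich domain superfamily protein	0.967857143
A0A3Q7G7J3	protein	NA	0.967857143
Solyc05g006110.3	transcript	Serine/Threonine-kinase	0.971428571
Solyc10g005870.4	transcript	Peptidylprolyl isomerase	0.971428571
Solyc09g010110.3	transcript	Chaperone protein dnaJ-related protein	0.975
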