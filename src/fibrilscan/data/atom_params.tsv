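# per-element atom parameters for SASA and the CrossBetaPotential surrogate
# radius: van der Waals radius (A); epsilon: LJ well depth (energy units);
# sigma_solv: atomic solvation parameter (energy units per A^2 of exposed area)
element	radius	epsilon	sigma_solv
C	1.70	0.120	0.016
N	1.55	0.160	-0.012
O	1.52	0.200	-0.018
S	1.80	0.250	0.012
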