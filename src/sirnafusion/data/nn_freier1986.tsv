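# RNA/RNA Watson-Crick nearest-neighbor stacking free energies, dG37 in kcal/mol
# (Freier et al. 1986 parameter set). Key is the 5'->3' dinucleotide on one strand;
# the paired strand is its Watson-Crick complement. Self-consistent under strand
# symmetry: value(XY) == value(revcomp(XY)).
# name	freier1986
# init	3.4
stack	AA	-0.9
stack	AC	-2.1
stack	AG	-1.7
stack	AU	-0.9
stack	CA	-1.8
stack	CC	-2.9
stack	CG	-2.0
stack	CU	-1.7
stack	GA	-2.3
stack	GC	-3.4
stack	GG	-2.9
stack	GU	-2.1
stack	UA	-1.1
stack	UC	-2.3
stack	UG	-1.8
stack	UU	-0.9
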