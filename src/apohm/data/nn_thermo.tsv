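# DNA nearest-neighbor thermodynamic parameters, delta-G at 37 C (kcal/mol).
# This file is the source of truth for hairpin scoring and may be swapped for
# an alternative parameter set with the same layout.
# category	key	delta_g
# stack keys are 5'-XY-3'/3'-ZW-5' frames; symmetric duplex equivalents are
# expanded at load time.
stack	AA/TT	-1.00
stack	AT/TA	-0.88
stack	TA/AT	-0.58
stack	CA/GT	-1.45
stack	GT/CA	-1.44
stack	CT/GA	-1.28
stack	GA/CT	-1.30
stack	CG/GC	-2.17
stack	GC/CG	-2.24
stack	GG/CC	-1.84
# hairpin-loop initiation penalty by loop size (closing pair excluded)
hairpin_loop	3	3.50
hairpin_loop	4	3.50
hairpin_loop	5	3.30
hairpin_loop	6	4.00
hairpin_loop	7	4.20
hairpin_loop	8	4.30
hairpin_loop	9	4.50
hairpin_loop	10	4.40
# sequence-specific increments for small loops; key = 5' closing base + loop
# sequence + 3' closing base
triloop	AGAAT	-1.50
triloop	CGAAG	-2.00
triloop	GTTCG	-1.50
tetraloop	CGAAAG	-2.00
tetraloop	GGAAAC	-1.50
tetraloop	CTTCGG	-1.20
# defect increments: one internal non-Watson-Crick pair, or a single-nucleotide
# bulge (the stack across a 1-nt bulge is retained)
mismatch	any	1.00
bulge	1	4.00
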