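# Step 2 (phosphoaspartate hydrolysis): printed stationary-state distances
# (Å) from the 1D and 2D constrained potential-energy scans, with the
# tabulated reaction-coordinate values they imply.
# rc1 = OPO_step2 = d(P-O-Asp11) - d(Wat-O-P)
# rc2 in the 2D block follows the oho_defn column: the rows are arithmetically
# consistent with OHO_step2 = d(Wat-O-H) - d(H-OT-Asp11), not with the
# OHO_step2_asp13 variant.
block	state	rc1	rc2	oho_defn	exact_rc1	exact_rc2	P-O-Asp11	Wat-O-P	H-OD-Asp13	Wat-O-H	H-OT-Asp11
1d_scan	IM	-1.5			1		1.75	3.25	2.06	0.97	2.88
1d_scan	TS	1.1			1		3.04	1.95	1.57	1.02	2.38
1d_scan	P	1.6			1		3.30	1.68	1.52	2.90	1.02
2d_scan_opo_oho	IM	-1.5	-1.0	OHO_step2	1	1	1.75	3.25	2.83	0.96	1.95
2d_scan_opo_oho	TS	1.4	-0.3	OHO_step2	1	1	3.20	1.76	1.15	1.35	1.62
2d_scan_opo_oho	P	1.5	1.0	OHO_step2	1	1	3.24	1.73	1.66	1.97	0.98
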