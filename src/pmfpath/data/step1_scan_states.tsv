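# Step 1 (serine -> Asp11 phosphoryl transfer): printed stationary-state
# distances (Å) from the 1D and 2D constrained potential-energy scans, with
# the tabulated reaction-coordinate values they imply.
# rc1 = OPO_step1 = d(Ser-OG-P) - d(P-O-Asp11)
# rc2 = OHO_step1 = -d(Ser-OG-H) + d(H-OD-Asp13)   (2D block only)
# exact_rc*: 1 if the signed distance sum rounds (half-up, 1 decimal) to the
# printed rc; 0 where the printed row is internally inconsistent by one unit
# in the last decimal.
block	state	rc1	rc2	exact_rc1	exact_rc2	Ser-OG-P	P-O-Asp11	H-OD-Asp13	Ser-OG-H	Ser-OT-H
1d_scan	IM	-1.5		1		1.72	3.25	1.03	2.44	1.54
1d_scan	TS	-0.9		1		2.04	2.94	1.60	1.02	2.84
1d_scan	P	1.2		1		3.09	1.87	1.76	0.99	3.52
2d_scan_opo_oho	IM	-1.5	-0.7	1	1	1.74	3.24	1.00	1.70	2.38
2d_scan_opo_oho	TS	-1.3	0.0	1	1	1.84	3.14	1.31	1.31	2.77
2d_scan_opo_oho	P	1.2	0.7	1	0	3.09	1.87	1.75	0.97	3.50
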