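lg	single_marker_loci	bin_loci	total_loci	mapped_markers	coverage_cm
A01	62	32	94	274	91
A02	75	21	96	189	72.3
A03	72	26	98	163	94.9
A04	48	13	61	133	63.3
A05	71	24	95	150	94.4
A06	80	25	105	160	98.2
A07	40	31	71	163	71.5
A08	59	26	85	177	66.4
A09	62	38	100	311	108
A10	71	12	83	144	68.4
B01	41	26	67	171	62.8
B02	67	39	106	236	105.1
B03	69	17	86	230	59.8
B04	66	17	83	139	115.4
B05	51	19	70	125	102.2
B06	50	11	61	79	75.8
B07	60	39	99	246	102.2
B08	88	22	110	239	126.7
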