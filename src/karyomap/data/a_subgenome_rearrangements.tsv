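chrom	inv_Aj-Ar_total	inv_Aj-Ar_small	inv_Aj-An_total	inv_Aj-An_small	inv_An-Ar_total	inv_An-Ar_small	trans_Aj-Ar	trans_Aj-An	trans_Ar>An	trans_An>Ar
A01	2	2	2	2	6	3	0	0	0	3
A02	3	2	2	1	7	6	0	0	0	4
A03	0	0	2	0	4	3	0	0	2	1
A04	2	0	1	0	4	4	1	1	0	0
A05	1	0	0	0	10	7	0	1	4	3
A06	1	1	1	1	3	2	0	0	1	0
A07	1	0	1	0	11	10	0	0	3	0
A08	1	0	1	0	3	3	0	1	4	2
A09	1	1	2	1	8	5	0	0	1	0
A10	1	0	3	2	6	4	1	0	0	2
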