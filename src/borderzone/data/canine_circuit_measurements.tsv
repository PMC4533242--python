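# Unidirectional block line / isthmus overlap measurements for 12 canine
# postinfarction mapping experiments.  Columns: lengths a-d in mm, d/c in
# percent.  Published per-experiment values; means/SDs are recomputed, not
# shipped.
a	b	c	d	d_over_c	expt
43.63	9.44	20.57	5.54	26.93	1
11.90	5.36	10.94	6.43	58.74	2
56.42	24.57	42.58	18.92	44.44	3
38.97	6.41	12.44	3.94	31.64	4
38.61	18.44	18.48	6.49	35.14	5
26.39	8.82	16.72	6.91	41.31	6
23.91	11.79	30.38	13.85	45.58	7
40.27	4.48	18.65	4.81	25.78	8
25.62	8.44	25.44	11.38	44.71	9
19.81	12.41	35.52	13.23	37.24	10
8.87	7.72	25.79	7.10	27.54	11
41.94	10.51	19.88	8.42	42.34	12
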