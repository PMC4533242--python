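# Cycle-length measurements for 12 canine postinfarction mapping
# experiments.  ps: premature (S1-S2) coupling interval leading to reentry;
# vt: mean cycle length of the first 10 reentry beats; reexcitation:
# interval between premature-cycle and first-reentry-cycle activation at
# the breakthrough site.  All ms.
ps	vt	reexcitation	expt
160	183	171	1
160	197	159	2
170	217	113	3
160	182	140	4
140	167	133	5
160	174	167	6
170	177	103	7
180	185	145	8
175	221	156	9
175	220	184	10
170	202	147	11
155	163	193	12
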