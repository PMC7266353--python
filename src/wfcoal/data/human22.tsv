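# wfcoal human-like autosome map, version 1
# Sex-averaged genetic lengths of the 22 human autosomes, in Morgans,
# rounded from commonly used linkage-map totals. Synthetic fixture: values
# are realistic but not tied to any specific published map release.
chromosome	genetic_length_morgans
1	2.863
2	2.688
3	2.234
4	2.146
5	2.041
6	1.920
7	1.872
8	1.680
9	1.664
10	1.811
11	1.582
12	1.747
13	1.259
14	1.202
15	1.419
16	1.340
17	1.285
18	1.175
19	1.079
20	1.083
21	0.628
22	0.741
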