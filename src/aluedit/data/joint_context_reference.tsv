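context	freq	enrichment	n_sites
G,T:A	0.005	0.054	407
G,T:G	0.006	0.066	501
G,C:A	0.006	0.069	160
G,C:G	0.007	0.081	273
G,G:G	0.007	0.081	545
A,C:G	0.014	0.156	213
G,A:G	0.016	0.174	190
C,C:G	0.019	0.207	319
C,T:G	0.019	0.213	362
G,C:C	0.021	0.226	1268
C,T:A	0.022	0.240	412
G,G:A	0.023	0.256	1078
C,A:A	0.024	0.265	334
A,A:A	0.026	0.288	422
G,A:C	0.026	0.292	981
A,A:G	0.030	0.335	461
A,T:G	0.033	0.367	210
T,T:A	0.033	0.368	449
G,T:C	0.034	0.370	1016
T,T:G	0.035	0.383	202
C,C:A	0.037	0.408	784
T,C:G	0.041	0.454	170
G,A:A	0.042	0.468	118
C,A:G	0.044	0.481	528
C,G:G	0.046	0.506	567
A,T:A	0.055	0.608	236
A,C:A	0.059	0.651	339
G,G:C	0.067	0.737	1482
C,G:A	0.068	0.753	966
T,C:A	0.072	0.792	209
A,A:C	0.094	1.035	1226
T,A:G	0.096	1.063	197
T,A:A	0.104	1.149	96
T,G:G	0.110	1.209	228
C,T:C	0.129	1.421	1203
A,G:G	0.144	1.587	278
T,G:A	0.148	1.629	474
C,C:C	0.163	1.801	2321
A,G:A	0.166	1.825	278
C,A:C	0.174	1.923	1515
A,C:C	0.193	2.132	1314
A,T:C	0.248	2.740	1610
C,G:C	0.257	2.839	2797
A,G:C	0.268	2.952	1364
T,T:C	0.269	2.967	788
T,C:C	0.271	2.994	818
T,A:C	0.284	3.138	689
T,G:C	0.374	4.123	1589
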