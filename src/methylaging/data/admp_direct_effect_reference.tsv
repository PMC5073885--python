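chrom	pos	adj_p	diff_2_10	diff_10_16	diff_2_16	gene	in_cgi	replicated
chr16	9596098	0.0066	-0.0245	-0.0697	-0.0941	.	No	no
chr1	156883344	0.0001	0.3168	0.0722	0.3891	PEAR1	No	yes
chr1	156883372	0.0463	0.1817	0.0111	0.1928	PEAR1	No	yes
chr12	28400131	0.0263	0.2586	0.1004	0.3590	OBSNC	Yes	no
chr12	28400135	0.0401	0.1595	0.0644	0.2239	OBSNC	Yes	no
chr12	28400157	0.0463	0.2250	0.0287	0.2537	OBSNC	Yes	no
chr12	28400210	0.0271	0.1841	0.0520	0.2361	OBSNC	Yes	no
chr12	28400285	0.0427	0.2845	0.1512	0.4356	OBSNC	Yes	no
chr2	233251546	0.0263	0.3498	0.0427	0.3926	ECEL1P2	Yes	no
chr2	233251551	0.0097	0.3378	0.0274	0.3652	ECEL1P2	Yes	no
chr4	117279915	0.0066	-0.1557	-0.1123	-0.2681	.	No	no
chr4	117280012	0.0284	-0.2395	-0.0671	-0.3066	.	No	no
chr5	78985800	0.0455	0.1730	0.1003	0.2732	CMYA5	No	yes
chr6	158097037	0.0409	0.2276	0.0110	0.2386	.	No	no
chr7	100463812	0.0254	-0.3432	-0.0831	-0.4262	TRIP6	Yes	yes
chr8	6656321	0.0090	-0.1563	-0.0884	-0.2447	.	No	no
chr9	136474402	0.0263	0.0524	0.0942	0.1466	.	Yes	no
chr9	140173334	0.0066	0.2576	0.0925	0.3501	C9orf167	Yes	no
chr9	140173378	0.0229	0.0922	0.0555	0.1477	C9orf167	Yes	no
chr10	129537308	0.0066	0.3634	0.0584	0.4218	FOX12	Yes	no
chr14	105881000	0.0263	0.0370	0.0214	0.0584	.	No	no
chr17	1179934	0.0344	-0.1037	-0.1406	-0.2443	TUSC5	No	no
chr17	75421287	0.0463	0.0196	0.0271	0.0467	SEPT9	No	no
chr17	76355061	0.0066	0.2076	0.1098	0.3174	SOCS3	Yes	yes
chr17	78262132	0.0486	0.1670	0.0400	0.2069	RNF213	No	no
chr20	62679572	0.0401	0.1111	0.0882	0.1993	SOX18	Yes	yes
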