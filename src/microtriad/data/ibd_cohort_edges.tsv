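node_a	modality_a	node_b	modality_b	log10_bf	rho
Odoribacter	T	Pectin degradation	M	2.026	0.455
Odoribacter	T	HADS-D	PP	1.956	-0.457
Pectin degradation	M	HADS-D	PP	0.804	-0.343
Odoribacter	T	PRPP biosynthesis	M	1.291	-0.390
Odoribacter	T	HADS-D	PP	1.956	-0.457
PRPP biosynthesis	M	HADS-D	PP	0.655	0.324
Odoribacter	T	Dermatan sulfate degradation	M	2.611	0.498
Odoribacter	T	HADS-D	PP	1.956	-0.457
Dermatan sulfate degradation	M	HADS-D	PP	0.530	-0.307
Alistipes	T	Dermatan sulfate degradation	M	1.644	0.423
Alistipes	T	HADS-D	PP	0.997	-0.365
Dermatan sulfate degradation	M	HADS-D	PP	0.530	-0.307
Anaerotruncus	T	Dermatan sulfate degradation	M	1.098	0.370
Anaerotruncus	T	HADS-D	PP	0.530	-0.307
Dermatan sulfate degradation	M	HADS-D	PP	0.666	-0.326
Intestinimonas	T	Methionine biosynthesis	M	0.509	-0.300
Intestinimonas	T	WEIMuS	PP	0.972	-0.363
Methionine biosynthesis	M	WEIMuS	PP	0.959	0.361
Eubacterium	T	Pentose phosphate pathway	M	1.082	-0.369
Eubacterium	T	WEIMuS	PP	0.655	-0.324
Pentose phosphate pathway	M	WEIMuS	PP	0.715	0.332
Anaerotruncus	T	Pentose phosphate pathway	M	0.554	-0.306
Anaerotruncus	T	WEIMuS	PP	0.662	-0.325
Pentose phosphate pathway	M	WEIMuS	PP	0.715	0.332
Clostridiales g.i.s.	T	Pentose phosphate pathway	M	2.900	-0.517
Clostridiales g.i.s.	T	WEIMuS	PP	0.660	-0.325
Pentose phosphate pathway	M	WEIMuS	PP	0.715	0.332
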