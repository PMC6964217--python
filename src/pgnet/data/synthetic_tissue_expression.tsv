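# Synthetic tissue-expression fixture for the ternary-network miRNAs
# (two planted expression blocks; values are arbitrary units).
mirna_id	stomach	kidney	liver	spleen	bone	myocardium	muscle	colon	thyroid	artery
miR-181b	8.745	7.869	7.925	7.791	7.771	2.523	3.422	2.953	2.949	2.688
miR-195	7.729	8.475	7.480	7.608	8.443	2.856	2.736	2.525	2.961	2.254
miR-214-3p	7.881	7.935	7.658	8.111	7.756	3.033	3.023	3.745	3.420	2.954
miR-647	7.910	7.846	7.711	8.017	8.223	3.355	2.832	3.426	1.829	2.921
miR-214	8.508	8.126	7.675	7.065	7.879	3.233	2.940	3.241	2.858	2.965
miR-130a-3p	8.410	7.885	7.839	7.095	7.079	2.530	3.011	3.030	2.994	3.507
miR-1	8.334	7.431	7.536	8.292	8.152	3.264	1.914	2.326	2.711	4.005
miR-185-5p	7.688	8.314	7.321	8.179	8.252	2.453	2.823	2.916	2.817	2.859
miR-103	3.202	2.969	2.579	3.772	2.947	8.516	8.635	7.533	8.287	8.753
miR-107	3.170	3.681	3.213	2.582	2.501	9.139	7.826	8.404	7.343	7.458
miR-133a	2.620	3.864	2.327	2.574	3.020	7.662	8.071	7.927	8.375	7.424
miR-2499	3.704	2.909	2.928	2.529	3.127	8.135	7.790	7.889	8.119	7.641
miR-30c	3.657	3.024	2.463	2.727	3.666	8.155	7.797	7.988	7.607	7.915
let-7e	2.332	2.628	3.548	3.241	3.043	7.691	8.530	8.686	7.401	7.766
miR-143	3.273	2.150	3.076	3.147	3.866	7.582	7.234	8.690	8.993	7.851
miR-221	3.013	4.105	3.299	2.785	2.770	8.889	8.743	7.635	8.415	8.366
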