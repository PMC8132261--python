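locus	category	phenotype	p_gwas	pph4_gwas	pph4_eqtl	egenes
1:154605882–155673527	Two GWAS signals one for susceptibility, one for severity	A2	3.93E-07	0.993	0.852
1:154605882–155673527	Two GWAS signals one for susceptibility, one for severity	B1	1.26E-03	0.006	0.042
1:154605882–155673527	Two GWAS signals one for susceptibility, one for severity	B2	1.02E-08	0.997	0.892
1:154605882–155673527	Two GWAS signals one for susceptibility, one for severity	C2	1.02E-08	0.988	0.943	FAM189B
2:166418293–167418293	Severity	A2	3.73E-05	0.057	0.032
2:166418293–167418293	Severity	B1	6.33E-04	0.005	0.092
2:166418293–167418293	Severity	B2	6.01E-08	0.985	0.261
2:166418293–167418293	Severity	C2	1.60E-05	0.057	0.102
3:45137109–47151986	Two GWAS signals, both for severity	A2	2.70E-49	0.992	0.645
3:45137109–47151986	Two GWAS signals, both for severity	B1	3.44E-11	0.970	0.788
3:45137109–47151986	Two GWAS signals, both for severity	B2	4.83E-62	0.993	0.654
3:45137109–47151986	Two GWAS signals, both for severity	C2	3.61E-25	0.998	0.882
3:100646362–102035347	Susceptibility	A2	3.83E-04	0.004	0.012
3:100646362–102035347	Susceptibility	B1	1.86E-04	0.016	0.114
3:100646362–102035347	Susceptibility	B2	3.09E-04	0.001	0.097
3:100646362–102035347	Susceptibility	C2	3.51E-10	0.955	0.948	CEP97; NXPE3; PDCL3P4
3:196626406–197627009	Severity	A2	3.15E-08	0.996	0.331
3:196626406–197627009	Severity	B1	2.66E-04	0.025	0.116
3:196626406–197627009	Severity	B2	1.44E-04	0.017	0.087
3:196626406–197627009	Severity	C2	2.14E-05	0.021	0.160
5:91295333–92295333	Susceptibility	A2	6.04E-04	0.005	0.003
5:91295333–92295333	Susceptibility	B1	5.06E-04	0.025	0.017
5:91295333–92295333	Susceptibility	B2	5.52E-06	0.904	0.013
5:91295333–92295333	Susceptibility	C2	8.73E-08	0.918	0.330
6:30620729–31621958	Susceptibility	A2	7.31E-13	0.997	0.957	TCF19
6:30620729–31621958	Susceptibility	B1	1.27E-03	0.009	0.107
6:30620729–31621958	Susceptibility	B2	2.26E-10	0.997	0.958	TCF19
6:30620729–31621958	Susceptibility	C2	1.60E-07	0.989	0.946	TCF19
6:32555355–33555355	Severity	A2	2.61E-08	0.999	0.990	HLA-DPA2
6:32555355–33555355	Severity	B1	5.78E-04	0.024	0.123
6:32555355–33555355	Severity	B2	1.36E-06	0.708	0.944	HLA-DPA2
6:32555355–33555355	Severity	C2	1.53E-05	0.105	0.347
6:40997035–42005196	Severity; Ethnicity-specific signal	A2	1.44E-05	0.381	0.202
6:40997035–42005196	Severity; Ethnicity-specific signal	B1	3.66E-04	0.057	0.417
6:40997035–42005196	Severity; Ethnicity-specific signal	B2	3.44E-08	0.996	0.921	FOXP4
6:40997035–42005196	Severity; Ethnicity-specific signal	C2	1.44E-06	0.878	0.743
7:35938709–36938709	Severity	A2	4.46E-05	0.010	0.043
7:35938709–36938709	Severity	B1	1.32E-04	0.224	0.094
7:35938709–36938709	Severity	B2	5.70E-08	0.996	0.771
7:35938709–36938709	Severity	C2	5.25E-05	0.019	0.200
7:54147894–55147894	Severity	A2	6.86E-11	1.000	0.012
7:54147894–55147894	Severity	B1	1.56E-04	0.088	0.252
7:54147894–55147894	Severity	B2	3.64E-09	1.000	0.009
7:54147894–55147894	Severity	C2	9.49E-04	0.000	0.011
7:107107902–108107902	Severity	A2	2.41E-09	1.000	0.290
7:107107902–108107902	Severity	B1	6.75E-04	0.007	0.070
7:107107902–108107902	Severity	B2	3.48E-05	0.038	0.014
7:107107902–108107902	Severity	C2	7.62E-04	0.001	0.014
8:124836564–125836564	Severity; Ethnicity-specific signal	A2	2.67E-05	0.335	0.009
8:124836564–125836564	Severity; Ethnicity-specific signal	B1	2.31E-04	0.113	0.173
8:124836564–125836564	Severity; Ethnicity-specific signal	B2	2.64E-08	0.999	0.366
8:124836564–125836564	Severity; Ethnicity-specific signal	C2	2.20E-03	0.000	0.007
9:135628546–136796530	Susceptibility	A2	1.20E-07	0.968	0.832
9:135628546–136796530	Susceptibility	B1	6.40E-05	0.102	0.589
9:135628546–136796530	Susceptibility	B2	4.42E-09	0.990	0.999	ABO
9:135628546–136796530	Susceptibility	C2	1.36E-24	0.999	1.000	ABO
11:97265524–98293951	Severity	A2	5.68E-08	0.981	0.010
11:97265524–98293951	Severity	B1	2.01E-04	0.008	0.009
11:97265524–98293951	Severity	B2	7.72E-05	0.011	0.003
11:97265524–98293951	Severity	C2	2.92E-04	0.007	0.001
12:67595307–68600256	Severity	A2	1.68E-05	0.054	0.057
12:67595307–68600256	Severity	B1	2.62E-04	0.021	0.086
12:67595307–68600256	Severity	B2	5.27E-08	0.952	0.403
12:67595307–68600256	Severity	C2	1.20E-03	0.000	0.017
12:102514757–103514757	Severity	A2	3.01E-10	1.000	0.598
12:102514757–103514757	Severity	B1	6.23E-04	0.009	0.040
12:102514757–103514757	Severity	B2	3.43E-08	0.999	0.580
12:102514757–103514757	Severity	C2	1.76E-04	0.002	0.010
12:112850796–113925679	Susceptibility	A2	1.55E-13	0.980	0.989	OAS1
12:112850796–113925679	Susceptibility	B1	3.77E-05	0.291	0.082
12:112850796–113925679	Susceptibility	B2	4.91E-12	0.967	0.996	OAS1; OAS3
12:112850796–113925679	Susceptibility	C2	2.09E-11	0.985	0.998	OAS1; OAS3
15:100274021–101274021	Susceptibility; Ethnicity-specific signal	A2	7.59E-05	0.006	0.063
15:100274021–101274021	Susceptibility; Ethnicity-specific signal	B1	4.10E-05	0.356	0.197
15:100274021–101274021	Susceptibility; Ethnicity-specific signal	B2	3.71E-04	0.001	0.019
15:100274021–101274021	Susceptibility; Ethnicity-specific signal	C2	3.76E-08	0.998	0.156
17:43205356–45363133	Two GWAS signals, both for Severity	A2	5.84E-05	0.060	0.205
17:43205356–45363133	Two GWAS signals, both for Severity	B1	5.39E-08	0.973	0.993	ARL17B; LRRC37A; LRRC37A2; NSFP1
17:43205356–45363133	Two GWAS signals, both for Severity	B2	9.95E-10	0.444	0.592
17:43205356–45363133	Two GWAS signals, both for Severity	C2	2.95E-06	0.391	0.321
17:47368921–48440666	Severity	A2	8.53E-10	1.000	0.586
17:47368921–48440666	Severity	B1	3.51E-04	0.032	0.127
17:47368921–48440666	Severity	B2	1.90E-07	0.992	0.605
17:47368921–48440666	Severity	C2	2.33E-05	0.221	0.125
19:4184642–5224734	Susceptibility	A2	1.46E-21	0.999	0.914	PTPRS
19:4184642–5224734	Susceptibility	B1	9.37E-05	0.137	0.225
19:4184642–5224734	Susceptibility	B2	1.22E-17	1.000	0.925	PTPRS
19:4184642–5224734	Susceptibility	C2	2.28E-08	0.999	0.920	PTPRS
19:9927721–10977067	Severity	A2	1.92E-09	0.998	0.995	TYK2
19:9927721–10977067	Severity	B1	7.37E-05	0.324	0.750
19:9927721–10977067	Severity	B2	2.05E-10	0.998	0.994	TYK2
19:9927721–10977067	Severity	C2	6.05E-06	0.459	0.718
21:34089811–35134878	Susceptibility	A2	1.30E-14	0.995	0.985	AP000295.10; IFNAR2; IL10RB; IL10RB-AS1
21:34089811–35134878	Susceptibility	B1	7.50E-06	0.954	0.979	IFNAR2; IL10RB; IL10RB-AS1
21:34089811–35134878	Susceptibility	B2	4.11E-18	0.994	0.986	AP000295.10; IFNAR2; IL10RB; IL10RB-AS1
21:34089811–35134878	Susceptibility	C2	3.66E-09	0.998	0.956	IFNAR2; IL10RB; IL10RB-AS1
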