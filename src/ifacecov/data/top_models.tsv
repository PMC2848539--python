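target	template	log_e	q	q_dom	a_iden	a_sim	i_iden	i_sim	interface_rmsd	alternative
1avgH	1p3cA	-5.16	35.9		17.2	30.1	5.3	10.5	7.9	0
1fqjA	2g77B	-0.23	34.4	56.6	18.0	26.5	15.8	21.1	3.7	0
1g4uS	1he1A	-19.00	31.6	90.3	26.5	42.2	34.5	44.8	1.5	0
1gc1C	2z35A	-0.75	39.5		20.3	33.8	12.5	29.2	10.4	0
1gxdA	1pex0	-47.70	32.3	100.0	34.3	52.0	17.5	45.0	2.2	0
1h2sA	1bctA	-12.05	29.8		37.3	58.2	23.8	57.1	19.4	0
1i8lA	1h5bA	-2.70	39.9	77.4	10.5	29.1	5.6	27.8	7.4	0
1ixsB	2ewvA	-0.20	31.1	60.0	23.3	39.2	15.0	45.0	22.0	0
1kg0B	1b24A	-0.17	28.7	60.7	33.3	42.6	35.7	35.7	16.9	0
1kshA	2it1A	-0.60	38.7		22.2	36.1	25.0	29.2	31.1	0
1ktkE	1cd8A	-0.96	38.5	80.3	17.2	37.4	11.5	26.9	5.6	0
1m9fD	1cm5A	-1.24	33.6		38.9	48.2	25.0	25.0	33.4	0
1mq8A	1t0pB	-6.00	28.2	100.0	36.6	51.2	40.0	60.0	1.3	0
1nexB	1flgA	-0.66	20.5		9.3	33.0	3.2	41.9	53.4	0
1nt2A	1sb8A	-0.75	39.1		12.4	32.6	6.5	19.4	8.6	0
1s3sB	1cz4A	-10.40	37.1		23.0	40.5	18.5	33.3	4.1	0
1txqB	2bp7A	-1.52	36.1		37.5	59.4	40.0	60.0	21.5	0
1z3gH	1fo0A	-0.43	38.9	73.4	28.9	46.4	35.7	57.1	5.0	0
2a19A	1sljA	-4.70	38.9	68.3	15.2	38.0	11.8	29.4	3.2	0
2assB	1nexB	-2.70	20.8		25.4	46.5	36.1	52.8	6.2	0
2bcjA	1a25A	-1.68	11.0		9.8	31.7	21.1	31.6	48.7	0
2bcjQ	2g77B	-0.55	38.8	65.9	17.6	31.0	14.3	23.8	8.5	0
2bcjQ	1z0aA	-0.48	33.4	62.1	14.4	28.0	4.8	9.5	3.8	1
2bkkA	2j51A	-0.77	35.6		13.7	22.1	15.0	30.0	32.5	0
2c5dC	1i85A	-0.35	36.4	68.9	22.2	32.1	10.4	17.2	18.5	0
2c5dC	1k8iB	-2.52	39.0	73.8	14.3	29.9	3.5	13.8	4.9	1
2gy7B	1wgtA	-1.92	37.8		11.0	17.2	0.0	5.3	30.8	0
2mtaC	1gpeA	-1.23	38.1		14.3	26.8	16.7	33.3	22.7	0
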