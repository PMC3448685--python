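gene	probe	utr_snp	mirna	mi_snp	p	levene_q	weighted_p
RFPL1	ILMN_1797383	rs13053624	hsa-mir-592	rs11563750	1.04e-35	3.22e-5	1.50e-36
RFPL1	ILMN_1797383	rs13053624	hsa-mir-3920	rs12275715	1.21e-26	3.22e-5	1.74e-27
TXNDC5	ILMN_1769082	rs8643	hsa-mir-125b-2	rs2823897	8.95e-18	3.39e-1	1.23e-17
TXNDC5	ILMN_1769082	rs1043784	hsa-mir-125b-2	rs2823897	1.26e-17	3.18e-1	1.64e-17
LYZ	ILMN_1815205	rs710794	hsa-mir-1279	rs1463335	4.13e-15	4.51e-23	1.20e-16
ASB1	ILMN_1683096	rs1044561	hsa-mir-125b-2	rs2823897	1.45e-16	8.91e-1	1.87e-15
RFPL1	ILMN_1797383	rs13053624	hsa-mir-4656	rs3750013	2.28e-14	3.22e-5	3.29e-15
ASB1	ILMN_1683096	rs2278768	hsa-mir-3119-1	rs17349873	3.71e-14	1.34e-6	4.10e-15
RFPL1	ILMN_1797383	rs13053624	hsa-mir-30c-1	rs16827546	2.89e-14	3.22e-5	4.16e-15
ECE1	ILMN_1672174	rs3026907	hsa-mir-1307	rs7911488	2.98e-13	9.07e-46	4.29e-15
RFPL1	ILMN_1797383	rs13053624	hsa-mir-125b-1	rs2081443	2.40e-13	3.22e-5	3.47e-14
PKD1L2	ILMN_1742788	rs1901818	hsa-mir-4272	rs9868022	8.92e-14	8.80e-2	5.47e-14
ECE1	ILMN_1672174	rs3026907	hsa-mir-4670	rs2104533	5.16e-12	9.07e-46	7.42e-14
ASB1	ILMN_1683096	rs2278768	hsa-mir-125b-2	rs2823897	5.30e-12	1.34e-6	5.85e-12
RFPL1	ILMN_1797383	rs13053624	hsa-mir-4300	rs11603185	2.02e-11	3.22e-5	2.92e-12
SPRY1	ILMN_2329914	rs300574	hsa-mir-4666	rs16841344	1.52e-11	1.16e-2	5.10e-12
HLA-DPB1	ILMN_1749070	rs1042448	hsa-mir-219-1	rs107822	1.26e-10	4.11e-8	1.11e-11
ASB1	ILMN_1683096	rs2278768	hsa-mir-4636	rs257095	1.09e-10	1.34e-6	1.20e-11
RFPL1	ILMN_1797383	rs13053624	hsa-mir-4292	rs2811749	1.98e-10	3.22e-5	2.86e-11
RFPL1	ILMN_1797383	rs13053624	hsa-mir-624	rs11156654	2.20e-10	3.22e-5	3.18e-11
GPRC5C	ILMN_1724211	rs2706527	hsa-mir-3667	rs135771	5.46e-9	5.08e-79	4.52e-11
H1F0	ILMN_1757467	rs1894644	hsa-mir-659	rs5750504	2.98e-10	1.30e-1	2.18e-10
ECE1	ILMN_1672174	rs3026907	hsa-mir-548n	rs1649215	1.64e-8	9.07e-46	2.37e-10
RFPL1	ILMN_1797383	rs13053624	hsa-mir-521-1	rs4803178	2.88e-9	3.22e-5	4.16e-10
GPRC5C	ILMN_2352090	rs2706527	hsa-mir-3667	rs135771	1.06e-7	6.63e-102	6.80e-10
GPRC5C	ILMN_2352090	rs2706527	hsa-mir-107	rs17481096	1.20e-7	6.63e-102	7.69e-10
HLA-DPB1	ILMN_1749070	rs1042448	hsa-mir-219-1	rs213210	8.98e-9	4.11e-8	7.88e-10
MXRA7	ILMN_1743836	rs10473	hsa-mir-490	rs6963819	2.66e-7	6.10e-167	1.04e-9
SPRY1	ILMN_1651610	rs300574	hsa-mir-4666	rs16841344	3.82e-9	6.28e-3	1.12e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-1236	rs403569	7.89e-9	3.22e-5	1.14e-9
GPRC5C	ILMN_2352090	rs2706527	hsa-mir-941-1	rs2427555	2.03e-7	6.63e-102	1.30e-9
POGZ	ILMN_2329309	rs3811409	hsa-mir-4666	rs16841344	2.24e-9	1.12e-1	1.53e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-4643	rs16884450	1.28e-8	3.22e-5	1.85e-9
ASB1	ILMN_1683096	rs1044561	hsa-mir-3973	rs262404	1.60e-10	8.91e-1	2.06e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-3646	rs11574730	1.70e-8	3.22e-5	2.45e-9
ECE1	ILMN_1672174	rs3026907	hsa-mir-4460	rs13171514	2.47e-7	9.07e-46	3.55e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-3674	rs7003112	2.55e-8	3.22e-5	3.67e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-1205	rs9649959	2.78e-8	3.22e-5	4.02e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-4656	rs17829969	2.82e-8	3.22e-5	4.07e-9
ECE1	ILMN_1672174	rs3026907	hsa-mir-4784	rs6709245	3.22e-7	9.07e-46	4.63e-9
AAK1	ILMN_1880387	rs13427243	hsa-mir-3667	rs135771	7.28e-9	1.04e-1	4.80e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-604	rs2368392	3.69e-8	3.22e-5	5.32e-9
ECE1	ILMN_1672174	rs3026907	hsa-mir-215	rs3820455	3.88e-7	9.07e-46	5.58e-9
RBM12	ILMN_1670841	rs6060539	hsa-mir-4755	rs2284385	4.06e-7	1.65e-47	5.62e-9
ECE1	ILMN_1672174	rs3026907	hsa-mir-2113	rs9375085	4.02e-7	9.07e-46	5.79e-9
RFPL1	ILMN_1797383	rs13053624	hsa-mir-1269b	rs7210937	4.93e-8	3.22e-5	7.10e-9
ECE1	ILMN_1672174	rs3026907	hsa-mir-4705	rs7337292	5.10e-7	9.07e-46	7.33e-9
PKD1L2	ILMN_1742788	rs1901818	hsa-mir-4473	rs16938058	1.24e-8	8.80e-2	7.60e-9
MRPL43	ILMN_1678974	rs2295716	hsa-mir-608	rs4919510	3.06e-7	9.68e-22	9.44e-9
ECE1	ILMN_1672174	rs3026907	hsa-mir-520d	rs2217653	6.62e-7	9.07e-46	9.52e-9
ASB1	ILMN_1683096	rs1044561	hsa-mir-4636	rs257095	7.57e-10	8.91e-1	9.74e-9
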