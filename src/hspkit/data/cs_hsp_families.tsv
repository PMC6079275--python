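gene_name	gene_id	source_model	aa	mw_kd	pi	contig	start	end	localization
Hsf	ENSCSAVG00000009385	PF00447	478	53.799	5.10	reftig_90	222523	223959	Nucl
Hsp20-1	ENSCSAVG00000000921	PF00011	193	21.408	5.87	reftig_312	2232	5579	Cyt_Nucl
Hsp20-2	ENSCSAVG00000000281	PF00011	217	25.248	6.25	reftig_401	102219	105165	Nucl
Hsp20-3	ENSCSAVG00000005534	PF00011	92	10.174	7.80	reftig_13	1062933	1063499	Cyt_Nucl
Hsp40-1	ENSCSAVG00000006976	PF01556	350	39.785	8.71	reftig_133	809856	812974	Nucl
Hsp40-2	ENSCSAVG00000007731	PF01556	217	24.300	9.19	reftig_60	1120943	1122012	Cyt_Nucl
Hsp40-3	ENSCSAVG00000003847	PF01556	403	45.319	6.48	reftig_35	634966	640598	Cyt
Hsp40-4	ENSCSAVG00000008972	PF01556	404	46.384	8.78	reftig_156	374311	380085	Cyt
Hsp40-5	ENSCSAVG00000008657	PF01556	325	35.659	9.10	reftig_26	1311834	1318124	Cyt
Hsp40-6	ENSCSAVG00000009142	PF01556	381	42.974	9.00	reftig_48	906751	907896	Cyt
Hsp60-1	ENSCSAVG00000004234	PF00118	546	60.739	6.71	reftig_21	629188	631061	Cyt
Hsp60-2	ENSCSAVG00000005041	PF00118	544	60.205	6.44	reftig_60	147642	149276	Cyt
Hsp60-3	ENSCSAVG00000008004	PF00118	543	59.472	6.37	reftig_26	1230151	1236766	Cyt
Hsp60-4	ENSCSAVG00000000012	PF00118	540	59.365	7.62	reftig_451	111719	120981	Cyt
Hsp60-5	ENSCSAVG00000003875	PF00118	539	58.952	5.86	reftig_13	310857	312476	Cyt
Hsp60-6	ENSCSAVG00000009661	PF00118	536	58.046	8.31	reftig_90	354806	357327	Cyt
Hsp60-7	ENSCSAVG00000008115	PF00118	576	62.425	5.50	reftig_77	2940210	2949992	Cyt
Hsp60-8	ENSCSAVG00000000669	PF00118	597	63.920	5.38	reftig_247	178990	187341	Mito
Hsp60-9	novel	PF00118	559	60.097	6.78	reftig_12	172148	173993	Cyt
Hsp60-10	ENSCSAVG00000000743	PF00118	537	58.655	5.29	reftig_239	115028	122573	Cyt
Hsp70-1	ENSCSAVG00000009801	PF00012	622	67.999	5.95	reftig_1	1998692	2000750	Mito
Hsp70-2	ENSCSAVG00000006429	PF00012	657	72.054	5.11	reftig_140	663164	666781	ER
Hsp70-3	ENSCSAVG00000004764	PF00012	655	71.629	5.26	reftig_117	237857	240895	Cyt
Hsp70-4	ENSCSAVG00000009296	PF00012	647	71.617	5.61	reftig_11	1397712	1399655	Nucl
Hsp70-5	ENSCSAVG00000008588	PF00012	644	71.216	5.34	reftig_49	1564826	1572778	Cyto_Nucl
Hsp70-6	ENSCSAVG00000010133	PF00012	496	54.367	5.85	reftig_58	2768858	2774321	Cyt
Hsp70-7	ENSCSAVG00000010360	PF00012	775	87.079	6.21	reftig_49	3005369	3016199	Cyt
Hsp70-8	ENSCSAVG00000009021	PF00012	587	65.851	8.70	reftig_27	631835	635495	Nucl
Hsp100	ENSCSAVG00000003312	PF00012	879	100.328		reftig_21	370847	391331	Nucl
Hsp90-1	ENSCSAVG00000002810	PF00183	721	82.703	4.82	reftig_11	207906	212165	Cyt
Hsp90-2	ENSCSAVG00000010760	PF00183	817	93.408	4.63	reftig_14	1223243	1229985	ER
Hsp90-3	ENSCSAVG00000005261	PF00183	714	81.136	5.64	reftig_76	499897	510992	Mito
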