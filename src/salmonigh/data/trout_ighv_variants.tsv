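# Per-gene SNP/indel counts for rainbow trout IGHV genes across 19 isogenic lines.
# class: functional | pseudogene. ns = non-silent SNPs (printed in parentheses for
# functional genes; not printed for pseudogenes -> NA). Names and coordinate pairs are
# verbatim from the printed table ("IGH IGHV10-47" stray token and reversed start/stop
# pairs for opposite-polarity genes are normalized at load). position_anomaly flags the
# two genes whose printed hyphen position duplicates a neighbour's (chr13 position 39,
# chr12 position 11); they are excluded from positional-renumbering checks.
chromosome	class	start	stop	name	snp	ns	indel	position_anomaly
chr12	functional	81322385	81322680	IGHV6D-76	2	1	0	0
chr12	functional	81335727	81336024	IGHV1D-73	2	2	0	0
chr12	functional	81339680	81339363	IGHV12D-71	1	0	0	0
chr12	functional	81365089	81365411	IGHV15D-69	0	0	0	0
chr12	functional	81365950	81366255	IGHV2D-68	0	0	0	0
chr12	functional	81395848	81396168	IGHV7D-62	0	0	0	0
chr12	functional	81397765	81398073	IGHV4D-60	0	0	0	0
chr12	functional	81422492	81422803	IGHV15D-54	0	0	0	0
chr12	functional	81436861	81437166	IGHV2D-50	0	0	0	0
chr12	functional	81438847	81439169	IGHV15D-49	0	0	0	0
chr12	functional	81464500	81464820	IGHV7D-45	0	0	0	0
chr12	functional	81465762	81466082	IGHV7D-44	0	0	0	0
chr12	functional	81466761	81467069	IGHV4D-43	0	0	0	0
chr12	functional	81493829	81494124	IGHV6D-40	0	0	0	0
chr12	functional	81529173	81529478	IGHV1D-35	0	0	0	0
chr12	functional	81561752	81562063	IGHV3D-30	0	0	0	0
chr12	functional	81568866	81569171	IGHV2D-28	0	0	0	0
chr12	functional	81595836	81596138	IGHV10D-26	2	0	0	0
chr12	functional	81605108	81605419	IGHV4D-24	1	0	0	0
chr12	functional	81618381	81618689	IGHV4D-23	2	2	0	0
chr12	functional	81649810	81650108	IGHV1D-17	5	3	0	0
chr12	functional	81653372	81653678	IGHV1D-16	0	0	0	0
chr12	functional	81661001	81661301	IGHV1D-15	0	0	0	0
chr12	functional	81675466	81675769	IGHV1D-12	2	2	0	0
chr12	functional	81696523	81696828	IGHV2D-11	1	0	0	0
chr12	functional	81700731	81701033	IGHV10D-9	0	0	0	0
chr12	functional	81705764	81706066	IGHV10D-7	2	1	0	0
chr12	functional	81717198	81717494	IGHV6D-5	3	2	0	0
chr12	functional	81737673	81737973	IGHV1D-4	0	0	0	0
chr12	pseudogene	81312817	81313128	IGHV16D-79	3	NA	0	0
chr12	pseudogene	81318367	81318661	IGHV15D-78	5	NA	1	0
chr12	pseudogene	81320821	81321111	IGHV1D-77	1	NA	0	0
chr12	pseudogene	81332711	81333058	IGHV3D-75	2	NA	2	0
chr12	pseudogene	81333678	81333986	IGHV1D-74	1	NA	0	0
chr12	pseudogene	81336977	81337276	IGHV4D-72	0	NA	0	0
chr12	pseudogene	81383887	81384159	IGHV1D-65	0	NA	0	0
chr12	pseudogene	81384684	81384968	IGHV6D-64	0	NA	0	0
chr12	pseudogene	81388213	81388533	IGHV1D-63	1	NA	1	0
chr12	pseudogene	81396766	81397086	IGHV7D-61	0	NA	0	0
chr12	pseudogene	81398323	81398601	IGHV1D-59	0	NA	0	0
chr12	pseudogene	81399513	81399812	IGHV4D-58	0	NA	0	0
chr12	pseudogene	81401688	81402032	IGHV12D-57	0	NA	0	0
chr12	pseudogene	81402044	81401727	IGHV12D-56	0	NA	0	0
chr12	pseudogene	81421382	81421689	IGHV16D-55	11	NA	0	0
chr12	pseudogene	81434530	81434810	IGHV2D-52	0	NA	0	0
chr12	pseudogene	81435683	81435988	IGHV2D-51	0	NA	0	0
chr12	pseudogene	81447972	81448244	IGHV1D-48	0	NA	0	0
chr12	pseudogene	81448773	81449068	IGHV6D-47	0	NA	0	0
chr12	pseudogene	81453306	81453632	IGHV1D-46	0	NA	0	0
chr12	pseudogene	81467316	81467588	IGHV1D-42	0	NA	0	0
chr12	pseudogene	81481949	81482241	IGHV16D-41	0	NA	0	0
chr12	pseudogene	81511235	81511555	IGHV1D-39	2	NA	0	0
chr12	pseudogene	81514353	81514683	IGHV1D-38	0	NA	0	0
chr12	pseudogene	81516973	81517272	IGHV4D-37	0	NA	0	0
chr12	pseudogene	81519248	81519565	IGHV12D-36	1	NA	1	0
chr12	pseudogene	81548116	81548425	IGHV16D-34	0	NA	0	0
chr12	pseudogene	81550863	81551152	IGHV16D-33	0	NA	0	0
chr12	pseudogene	81558855	81559137	IGHV15D-32	0	NA	0	0
chr12	pseudogene	81560796	81561107	IGHV12D-31	0	NA	0	0
chr12	pseudogene	81567432	81567712	IGHV2D-29	0	NA	0	0
chr12	pseudogene	81594924	81595202	IGHV6D-27	1	NA	0	0
chr12	pseudogene	81598873	81599174	IGHV1D-25	0	NA	0	0
chr12	pseudogene	81618939	81619217	IGHV1D-22	11	NA	2	0
chr12	pseudogene	81628800	81629081	IGHV1D-21	2	NA	0	0
chr12	pseudogene	81629835	81630118	IGHV8D-20	0	NA	0	0
chr12	pseudogene	81630920	81631246	IGHV6D-19	0	NA	0	0
chr12	pseudogene	81637541	81637838	IGHV6D-18	0	NA	0	0
chr12	pseudogene	81674597	81674901	IGHV4D-13	0	NA	0	0
chr12	pseudogene	81699366	81699678	IGHV6D-10	0	NA	0	0
chr12	pseudogene	81704399	81704711	IGHV6D-8	0	NA	0	0
chr12	pseudogene	81713243	81713531	IGHV6D-6	3	NA	1	0
chr12	pseudogene	81745526	81745784	IGHV1D-3	2	NA	0	0
chr12	pseudogene	81746308	81746602	IGHV9D-2	1	NA	0	0
chr12	pseudogene	81750741	81751044	IGHV16D-1	6	NA	2	0
chr12	pseudogene	81671030	81671329	IGHV1D-14	0	NA	0	0
chr12	pseudogene	81367086	81367437	IGHV1D-67	0	NA	0	0
chr12	pseudogene	81367599	81367922	IGHV15D-66	0	NA	0	0
chr12	pseudogene	81430263	81430605	IGHV15D-53	0	NA	0	0
chr12	pseudogene	81359137	81359442	IGHV1D-70	0	NA	0	0
chr12	pseudogene	81676641	81676923	IGHV5D-11	0	NA	0	1
chr13	functional	48030797	48031104	IGH IGHV10-47	2	1	0	0
chr13	functional	48034515	48034814	IGHV8-46	1	0	0	0
chr13	functional	48054181	48054484	IGHV1-42	0	0	0	0
chr13	functional	48073234	48073536	IGHV8-40	0	0	0	0
chr13	functional	48077115	48077414	IGHV1-39	1	1	0	0
chr13	functional	48082080	48082391	IGHV16-37	3	3	0	0
chr13	functional	48093298	48093597	IGHV1-36	0	0	0	0
chr13	functional	48104897	48105217	IGHV6-35	0	0	0	0
chr13	functional	48109683	48109994	IGHV14-33	0	0	0	0
chr13	functional	48122499	48122783	IGHV6-32	0	0	0	0
chr13	functional	48127168	48127466	IGHV6-31	0	0	0	0
chr13	functional	48135329	48135631	IGHV8-30	0	0	0	0
chr13	functional	48145742	48146047	IGHV2-28	7	3	0	0
chr13	functional	48148981	48149284	IGHV11-25	0	0	0	0
chr13	functional	48164983	48165317	IGHV9-23	4	3	0	0
chr13	functional	48166898	48167189	IGHV4-22	9	7	0	0
chr13	functional	48168162	48168465	IGHV1-21	5	3	0	0
chr13	functional	48174816	48175127	IGHV3-20	4	2	0	0
chr13	functional	48191970	48192272	IGHV8-19	6	5	0	0
chr13	functional	48201668	48201973	IGHV1-18	2	0	0	0
chr13	functional	48222441	48222126	IGHV9-16	1	1	1	0
chr13	functional	48223844	48223544	IGHV9-15	4	2	0	0
chr13	functional	48237588	48237899	IGHV16-14	6	6	0	0
chr13	functional	48243688	48243987	IGHV1-13	3	0	0	0
chr13	functional	48250487	48250789	IGHV1-10	0	0	0	0
chr13	functional	48257525	48257828	IGHV2-8	2	1	0	0
chr13	functional	48307972	48307670	IGHV8-5	7	2	0	0
chr13	functional	48312160	48311865	IGHV6-4	0	0	0	0
chr13	functional	48327417	48327761	IGHV1-2	0	0	0	0
chr13	pseudogene	48138071	48138427	IGHV8-29	0	NA	0	0
chr13	pseudogene	48027352	48027666	IGHV15-48	7	NA	0	0
chr13	pseudogene	48046874	48047207	IGHV9-45	1	NA	0	0
chr13	pseudogene	48048080	48048362	IGHV4-44	0	NA	0	0
chr13	pseudogene	48051342	48051671	IGHV1-43	2	NA	0	0
chr13	pseudogene	48068027	48068332	IGHV1-41	0	NA	0	0
chr13	pseudogene	48079966	48080277	IGHV16-38	1	NA	0	0
chr13	pseudogene	48108554	48108889	IGHV9-34	0	NA	0	0
chr13	pseudogene	48146928	48147231	IGHV2-27	3	NA	0	0
chr13	pseudogene	48147810	48148106	IGHV6-26	3	NA	0	0
chr13	pseudogene	48157816	48158168	IGHV9-24	5	NA	2	0
chr13	pseudogene	48211869	48212178	IGHV7-17	3	NA	0	0
chr13	pseudogene	48244719	48245034	IGHV10-12	3	NA	0	0
chr13	pseudogene	48245867	48246172	IGHV8-11	2	NA	0	0
chr13	pseudogene	48254879	48254570	IGHV16-9	0	NA	0	0
chr13	pseudogene	48279548	48279841	IGHV1-7	0	NA	0	0
chr13	pseudogene	48280387	48280681	IGHV4-6	4	NA	1	0
chr13	pseudogene	48316059	48315761	IGHV6-3	3	NA	0	0
chr13	pseudogene	48339577	48339885	IGHV4-1	0	NA	0	0
chr13	pseudogene	48076216	48076475	IGHV13-39	4	NA	0	1
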