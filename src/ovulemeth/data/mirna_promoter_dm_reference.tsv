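mirna	log2fc	direction	p_value	label
osa-miR1425-3p	-3.044394119	hypo	3.3523e-06	**
osa-miR1425-5p	-3.087462841	hypo	2.0804e-06	**
osa-miR1432-3p	1.874469118	hyper	0.026893	*
osa-miR1432-3p	1.044394119	hyper	0.00027986	**
osa-miR1432-5p	1.736965594	hyper	0.044044	*
osa-miR1435	1.169925001	hyper	0.039095	*
osa-miR156i	3.0	hyper	0.016686	*
osa-miR159d	-2.807354922	hypo	0.0034877	**
osa-miR160c-3p	-1.144389909	hypo	0.0052627	**
osa-miR160c-5p	-1.10433666	hypo	0.0061281	**
osa-miR166b-3p	1.502500341	hyper	0.016861	*
osa-miR166b-5p	1.736965594	hyper	0.0044014	**
osa-miR166c-3p	-3.169925001	hypo	0.013607	*
osa-miR166d-3p	-3.0	hypo	0.022957	*
osa-miR166d-5p	-3.0	hypo	0.022957	*
osa-miR166e-3p	1.584962501	hyper	0.0059267	**
osa-miR166e-5p	1.584962501	hyper	0.0059267	**
osa-miR167b	-1.125530882	hypo	0.037497	*
osa-miR167f	-1.263034406	hypo	0.022275	*
osa-miR169g	2.0	hyper	0.0055546	**
osa-miR169o	2.321928095	hyper	0.017365	*
osa-miR169r-3p	1.807354922	hyper	0.014604	*
osa-miR169r-5p	1.378511623	hyper	0.048778	*
osa-miR171c-3p	2.700439718	hyper	0.0035233	**
osa-miR171c-5p	2.584962501	hyper	0.0060011	**
osa-miR171d-3p	-2.321928095	hypo	0.025026	*
osa-miR171d-5p	-3.321928095	hypo	0.0080917	**
osa-miR172a	1.415037499	hyper	0.0016432	**
osa-miR1846c-3p	-1.044394119	hypo	0.022017	*
osa-miR1846c-5p	-1.044394119	hypo	0.022017	*
osa-miR1848	-1.754887502	hypo	0.0019694	**
osa-miR1850.2	1.321928095	hyper	0.039814	*
osa-miR1850.3	1.321928095	hyper	0.039814	*
osa-miR1859	1.584962501	hyper	0.037516	*
osa-miR2096-3p	-2.402098444	hypo	1.1225e-05	**
osa-miR2100-3p	1.192645078	hyper	0.048544	*
osa-miR2100-5p	-3.169925001	hypo	0.013607	*
osa-miR2275a	2.129283017	hyper	2.1442e-05	**
osa-miR2863b	1.736965594	hyper	0.044044	*
osa-miR2873a	2.906890596	hyper	0.001213	**
osa-miR2907c	-1.0	hypo	0.0018074	**
osa-miR2919	1.286881148	hyper	4.735e-05	**
osa-miR2932	-1.584962501	hypo	0.011048	*
osa-miR319a-3p.2-3p	-1.169925001	hypo	0.022704	*
osa-miR319a-3p.2-3p	-1.169925001	hypo	0.022704	*
osa-miR396b-3p	-1.584962501	hypo	0.0065944	**
osa-miR396b-5p	-1.222392421	hypo	0.016184	*
osa-miR396c-3p	-2.584962501	hypo	0.0093555	**
osa-miR396d	-1.201633861	hypo	0.031607	*
osa-miR3981-3p	1.137503524	hyper	0.025448	*
osa-miR3981-5p	1.070389328	hyper	0.036884	*
osa-miR399c	-1.485426827	hypo	0.047871	*
osa-miR399g	-1.247927513	hypo	0.043997	*
osa-miR399j	-2.169925001	hypo	0.040849	*
osa-miR415	-1.700439718	hypo	0.035614	*
osa-miR439c	-1.502500341	hypo	0.0018721	**
osa-miR439d	-1.874469118	hypo	3.647e-05	**
osa-miR5071	-1.321928095	hypo	0.030533	*
osa-miR5071	-2.321928095	hypo	0.025026	*
osa-miR5145	1.395928676	hyper	9.6668e-05	**
osa-miR5162	-1.440572591	hypo	0.024287	*
osa-miR5339	-4.058893689	hypo	2.731e-10	**
osa-miR5489	2.201633861	hyper	0.00045157	**
osa-miR5491	-2.584962501	hypo	0.001458	**
osa-miR5504	-1.874469118	hypo	0.039005	*
osa-miR5521	2.222392421	hyper	1.8915e-06	**
osa-miR5527	-1.029747343	hypo	0.0058305	**
osa-miR5533	-1.807354922	hypo	0.0013048	**
osa-miR5534b	1.184424571	hyper	0.014149	*
osa-miR5535	4.0	hyper	0.00019844	**
osa-miR5788	-1.0	hypo	0.0066162	**
osa-miR5789	1.906890596	hyper	0.0090287	**
osa-miR5791	-1.157541277	hypo	0.01925	*
osa-miR5810	-2.187627003	hypo	1.1529e-05	**
osa-miR5811	-1.874469118	hypo	0.039005	*
osa-miR5816	-1.222392421	hypo	0.007174	**
osa-miR5822	-1.0	hypo	0.0091971	**
osa-miR6251	3.321928095	hyper	0.005432	**
osa-miR812b	1.807354922	hyper	0.0027809	**
osa-miR812c	1.362570079	hyper	0.021442	*
osa-miR812e	-2.099535674	hypo	0.00025097	**
osa-miR812j	3.392317423	hyper	4.9436e-05	**
osa-miR812s	-1.362570079	hypo	0.035634	*
osa-miR821a	1.169925001	hyper	0.039095	*
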