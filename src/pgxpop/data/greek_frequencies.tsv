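population	rsid	allele_1	freq_1	allele_2	freq_2	n
Greek	rs1799853	C	0.856	T	0.144	3011
Greek	rs28371725	C	0.877	T	0.123	3011
Greek	rs2832407	A	0.336	C	0.664	3011
Greek	rs1414334	C	0.133	G	0.867	3011
Greek	rs1065852	A	0.200	G	0.800	3011
Greek	rs35742686	T	0.984	del	0.016	3011
Greek	rs28399504	A	0.995	G	0.005	3011
Greek	rs4244285	A	0.136	G	0.864	3011
Greek	rs5030656	CTTCT	0.991	CT	0.009	3011
Greek	rs1799978	C	0.078	T	0.922	3011
Greek	rs4713916	A	0.284	G	0.716	3011
Greek	rs5030655	A	0.993	del	0.007	3011
Greek	rs3892097	C	0.836	T	0.164	3011
Greek	rs4986893	G	0.999	A	0.001	3011
Greek	rs2234922	A	0.793	G	0.207	3011
Greek	rs1051740	C	0.293	T	0.707	3011
Greek	rs489693	A	0.307	C	0.693	3011
Greek	rs12248560	C	0.790	T	0.210	3011
Greek	rs7668258	C	0.524	T	0.476	3011
Greek	rs3812718	C	0.485	T	0.515	3011
Greek	rs1057910	A	0.906	C	0.094	3011
Greek	rs963468	A	0.375	G	0.625	3011
Greek	rs1800497	A	0.166	G	0.834	3011
Greek	rs17782313	C	0.244	T	0.756	3011
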