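PCNA_SIGNATURE	synthetic placeholder proliferation signature (r>0.65 criterion recorded as metadata)	PCNASIG001	PCNASIG002	PCNASIG003	PCNASIG004	PCNASIG005	PCNASIG006	PCNASIG007	PCNASIG008	PCNASIG009	PCNASIG010	PCNASIG011	PCNASIG012	PCNASIG013	PCNASIG014	PCNASIG015	PCNASIG016	PCNASIG017	PCNASIG018	PCNASIG019	PCNASIG020	PCNASIG021	PCNASIG022	PCNASIG023	PCNASIG024	PCNASIG025	PCNASIG026	PCNASIG027	PCNASIG028	PCNASIG029	PCNASIG030	PCNASIG031	PCNASIG032	PCNASIG033	PCNASIG034	PCNASIG035	PCNASIG036	PCNASIG037	PCNASIG038	PCNASIG039	PCNASIG040	PCNASIG041	PCNASIG042	PCNASIG043	PCNASIG044	PCNASIG045	PCNASIG046	PCNASIG047	PCNASIG048	PCNASIG049	PCNASIG050	PCNASIG051	PCNASIG052	PCNASIG053	PCNASIG054	PCNASIG055	PCNASIG056	PCNASIG057	PCNASIG058	PCNASIG059	PCNASIG060	PCNASIG061	PCNASIG062	PCNASIG063	PCNASIG064	PCNASIG065	PCNASIG066	PCNASIG067	PCNASIG068	PCNASIG069	PCNASIG070	PCNASIG071	PCNASIG072	PCNASIG073	PCNASIG074	PCNASIG075	PCNASIG076	PCNASIG077	PCNASIG078	PCNASIG079	PCNASIG080	PCNASIG081	PCNASIG082	PCNASIG083	PCNASIG084	PCNASIG085	PCNASIG086	PCNASIG087	PCNASIG088	PCNASIG089	PCNASIG090	PCNASIG091	PCNASIG092	PCNASIG093	PCNASIG094	PCNASIG095	PCNASIG096	PCNASIG097	PCNASIG098	PCNASIG099	PCNASIG100	PCNASIG101	PCNASIG102	PCNASIG103	PCNASIG104	PCNASIG105	PCNASIG106	PCNASIG107	PCNASIG108	PCNASIG109	PCNASIG110	PCNASIG111	PCNASIG112	PCNASIG113	PCNASIG114	PCNASIG115	PCNASIG116	PCNASIG117	PCNASIG118	PCNASIG119	PCNASIG120	PCNASIG121	PCNASIG122	PCNASIG123	PCNASIG124	PCNASIG125	PCNASIG126	PCNASIG127	PCNASIG128	PCNASIG129	PCNASIG130	PCNASIG131
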