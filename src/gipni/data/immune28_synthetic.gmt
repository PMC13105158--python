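Activated_B_cell	synthetic placeholder marker genes	IMM0001	IMM0002	IMM0003	IMM0004	IMM0005
Activated_CD4_T_cell	synthetic placeholder marker genes	IMM0006	IMM0007	IMM0008	IMM0009	IMM0010
Activated_CD8_T_cell	synthetic placeholder marker genes	IMM0011	IMM0012	IMM0013	IMM0014	IMM0015
Activated_dendritic_cell	synthetic placeholder marker genes	IMM0016	IMM0017	IMM0018	IMM0019	IMM0020
CD56bright_natural_killer_cell	synthetic placeholder marker genes	IMM0021	IMM0022	IMM0023	IMM0024	IMM0025
CD56dim_natural_killer_cell	synthetic placeholder marker genes	IMM0026	IMM0027	IMM0028	IMM0029	IMM0030
Central_memory_CD4_T_cell	synthetic placeholder marker genes	IMM0031	IMM0032	IMM0033	IMM0034	IMM0035
Central_memory_CD8_T_cell	synthetic placeholder marker genes	IMM0036	IMM0037	IMM0038	IMM0039	IMM0040
Effector_memory_CD4_T_cell	synthetic placeholder marker genes	IMM0041	IMM0042	IMM0043	IMM0044	IMM0045
Effector_memory_CD8_T_cell	synthetic placeholder marker genes	IMM0046	IMM0047	IMM0048	IMM0049	IMM0050
Eosinophil	synthetic placeholder marker genes	IMM0051	IMM0052	IMM0053	IMM0054	IMM0055
Gamma_delta_T_cell	synthetic placeholder marker genes	IMM0056	IMM0057	IMM0058	IMM0059	IMM0060
Immature_B_cell	synthetic placeholder marker genes	IMM0061	IMM0062	IMM0063	IMM0064	IMM0065
Immature_dendritic_cell	synthetic placeholder marker genes	IMM0066	IMM0067	IMM0068	IMM0069	IMM0070
Macrophage	synthetic placeholder marker genes	IMM0071	IMM0072	IMM0073	IMM0074	IMM0075
Mast_cell	synthetic placeholder marker genes	IMM0076	IMM0077	IMM0078	IMM0079	IMM0080
MDSC	synthetic placeholder marker genes	IMM0081	IMM0082	IMM0083	IMM0084	IMM0085
Memory_B_cell	synthetic placeholder marker genes	IMM0086	IMM0087	IMM0088	IMM0089	IMM0090
Monocyte	synthetic placeholder marker genes	IMM0091	IMM0092	IMM0093	IMM0094	IMM0095
Natural_killer_cell	synthetic placeholder marker genes	IMM0096	IMM0097	IMM0098	IMM0099	IMM0100
Natural_killer_T_cell	synthetic placeholder marker genes	IMM0101	IMM0102	IMM0103	IMM0104	IMM0105
Neutrophil	synthetic placeholder marker genes	IMM0106	IMM0107	IMM0108	IMM0109	IMM0110
Plasmacytoid_dendritic_cell	synthetic placeholder marker genes	IMM0111	IMM0112	IMM0113	IMM0114	IMM0115
Regulatory_T_cell	synthetic placeholder marker genes	IMM0116	IMM0117	IMM0118	IMM0119	IMM0120
T_follicular_helper_cell	synthetic placeholder marker genes	IMM0121	IMM0122	IMM0123	IMM0124	IMM0125
Type_1_T_helper_cell	synthetic placeholder marker genes	IMM0126	IMM0127	IMM0128	IMM0129	IMM0130
Type_17_T_helper_cell	synthetic placeholder marker genes	IMM0131	IMM0132	IMM0133	IMM0134	IMM0135
Type_2_T_helper_cell	synthetic placeholder marker genes	IMM0136	IMM0137	IMM0138	IMM0139	IMM0140
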