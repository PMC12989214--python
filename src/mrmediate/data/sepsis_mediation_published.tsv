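outcome	exposure	mediator	beta0	se0	beta1	se1	beta2	se2	indirect	indirect_se	proportion
Sepsis	family. Actinomycetaceae	Cer(d18:0/18:0)	0.165	0.076	0.205	0.096	0.101	0.040	0.021	0.013	0.125
Sepsis	genus. Dialister	Androsterone sulfate	-0.165	0.068	0.179	0.079	-0.071	0.018	-0.013	0.007	0.077
Sepsis	genus. Dialister	FAD	-0.165	0.068	-0.318	0.089	0.045	0.021	-0.014	0.008	0.086
Sepsis	genus. RuminococcaceaeUCG011	PC(34:4)	0.099	0.044	-0.130	0.048	-0.058	0.022	0.008	0.004	0.077
Sepsis	order. Actinomycetales	Cer(d18:0/18:0)	0.165	0.076	0.205	0.096	0.101	0.040	0.021	0.013	0.125
Sepsis (critical care)	class. Lentisphaeria/order. Victivallales	4-Hydroxyphenylacetic acid	-0.396	0.139	0.137	0.057	-0.242	0.115	-0.033	0.022	0.084
Sepsis (critical care)	class. Lentisphaeria/order. Victivallales	N-Acetyl-beta-alanine	-0.396	0.139	0.122	0.055	-0.163	0.073	-0.020	0.013	0.050
Sepsis (critical care)	phylum. Lentisphaerae	LysoPI(18:1 (9Z)/0:0)	-0.357	0.132	0.116	0.054	-0.289	0.091	-0.034	0.020	0.094
Sepsis (critical care)	phylum. Lentisphaerae	N-Acetyl-beta-alanine	-0.357	0.132	0.128	0.052	-0.163	0.073	-0.021	0.013	0.058
Sepsis (28-day death)	class. Bacteroidia/order. Bacteroidales	PE (P-18:0/18:1 (9Z))	0.395	0.168	-0.206	0.078	-0.213	0.097	0.044	0.027	0.111
Sepsis (28-day death)	class. Bacteroidia/order. Bacteroidales	Hexadecanedioic acid	0.395	0.168	-0.166	0.075	-0.131	0.050	0.022	0.013	0.055
Sepsis (28-day death)	class. Lentisphaeria/order. Victivallales	Gulonic acid	-0.389	0.118	0.139	0.054	-0.154	0.068	-0.021	0.013	0.055
Sepsis (28-day death)	class. Lentisphaeria/order. Victivallales	Maltotriose	-0.389	0.118	0.211	0.077	-0.142	0.068	-0.030	0.019	0.077
Sepsis (28-day death)	family. FamilyXIII	PC(34:4)	0.447	0.199	-0.240	0.094	-0.201	0.054	0.048	0.023	0.108
Sepsis (28-day death)	family. FamilyXIII	4-Trimethylammoniobutanoic acid	0.447	0.199	0.172	0.087	0.096	0.049	0.017	0.013	0.037
Sepsis (28-day death)	genus. Sellimonas	Eicosadienoic acid	0.222	0.094	0.094	0.045	0.227	0.114	0.021	0.016	0.096
Sepsis (28-day death)	genus. Sellimonas	4-Trimethylammoniobutanoic acid	0.222	0.094	0.093	0.042	0.096	0.049	0.009	0.006	0.040
Sepsis (28-day death)	genus. Terrisporobacter	Octadecenedioylcarnitine (C18:1-DC)	0.360	0.176	-0.182	0.080	-0.120	0.048	0.022	0.014	0.060
Sepsis (28-day death)	genus. Terrisporobacter	4-Trimethylammoniobutanoic acid	0.360	0.176	0.202	0.075	0.096	0.049	0.019	0.013	0.054
Sepsis (28-day death)	phylum. Lentisphaerae	Gulonic acid	-0.327	0.112	0.154	0.051	-0.154	0.068	-0.024	0.014	0.073
Sepsis (28-day death)	phylum. Lentisphaerae	Maltotriose	-0.327	0.112	0.195	0.073	-0.142	0.068	-0.028	0.018	0.085
Sepsis (28-day death in critical care)	class. Bacteroidia/order. Bacteroidales	17-Methyloctadecanoic acid	0.872	0.394	-0.170	0.077	-0.704	0.241	0.120	0.070	0.137
Sepsis (28-day death in critical care)	class. Bacteroidia/order. Bacteroidales	PE (P-18:0/18:1 (9Z))	0.872	0.394	-0.206	0.078	-0.465	0.230	0.096	0.062	0.110
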