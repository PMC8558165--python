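code,system,stream,category,subcategory,excluded_from_frequency
85.21,ICD9CM_PROC,HD,Surgery,Lumpectomy,False
85.22,ICD9CM_PROC,HD,Surgery,Lumpectomy,False
85.41,ICD9CM_PROC,HD,Surgery,Surgery,False
40.23,ICD9CM_PROC,HD,Surgery,Lymphadenectomy,False
85.53,ICD9CM_PROC,HD,Surgery,Plastic surgery,False
85.45,ICD9CM_PROC,HD,Surgery,Radical and reconstructive surgery,False
99.25,ICD9CM_PROC,HD,Chemotherapy,,False
92.29,ICD9CM_PROC,HD,Radiotherapy,,False
85.11,ICD9CM_PROC,HD,Diagnosis and monitoring,Biopsy,False
89.52,ICD9CM_PROC,HD,Diagnosis and monitoring,Cardiologic assessment,False
87.37,ICD9CM_PROC,HD,Diagnosis and monitoring,High diagnostic,False
87.44,ICD9CM_PROC,HD,Diagnosis and monitoring,Conventional radiology,False
99.04,ICD9CM_PROC,HD,Transfusion,,False
99.23,ICD9CM_PROC,HD,Support therapy,,False
174.9,ICD9CM_DIAG,HD,Diagnosis and monitoring,Diagnosis,False
V58.11,ICD9CM_DIAG,HD,Chemotherapy,,False
V58.0,ICD9CM_DIAG,HD,Radiotherapy,,False
V10.3,ICD9CM_DIAG,HD,Diagnosis and monitoring,Diagnosis,False
89.7,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Specialist examination,False
89.01,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Specialist examination,False
87.37.1,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,High diagnostic,False
88.73.1,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Ultrasonography,False
87.44.1,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Conventional radiology,False
85.11.1,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Biopsy,False
89.52,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Cardiologic assessment,False
92.24.1,OUTPATIENT_NATIONAL,OPS,Radiotherapy,,False
99.25.1,OUTPATIENT_NATIONAL,OPS,Chemotherapy,,False
93.39,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Physiatry,False
88.99.2,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Bone Densitometry,False
93.57.1,OUTPATIENT_NATIONAL,OPS,Post-surgical procedure,,False
94.3,OUTPATIENT_NATIONAL,OPS,Psychotherapy,,False
90.62.2,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Blood test,True
91.36.5,OUTPATIENT_NATIONAL,OPS,Diagnosis and monitoring,Genetic marker,True
L02BA01,ATC,DP,Hormone therapy,,False
L02BG04,ATC,DP,Hormone therapy,,False
L02BG03,ATC,DP,Hormone therapy,,False
H02AB02,ATC,DP,Cortisone,,False
H02AB07,ATC,DP,Cortisone,,False
A04AA01,ATC,DP,Antiemetic,,False
N02AB03,ATC,DP,Analgesic,,False
N02AA01,ATC,DP,Analgesic,,False
L03AA02,ATC,DP,Myelopoietic growth factor,,False
M05BA04,ATC,DP,Bisphosphonate,,False
L01BA01,ATC,DP,Chemotherapic drug,,False
B03XA01,ATC,DP,Hematopoietic growth factors,,False
L01XC03,ATC,HP,Chemotherapy,,False
L01CD01,ATC,HP,Chemotherapy,,False
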