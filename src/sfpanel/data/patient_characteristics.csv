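patient_id,age_collection,age_diagnosis,age_death,idc,ilc,her2,metastasis_sites,treatment
1,66,43,67,√,√,+,"Liver, lung, bone",Chemotherapy (carboplatin/gemzar)
2,57,56,58,√,×,−,"Liver, bone",Hormonal and Palbocyclib
3,36,27,37,√,×,−,"Bone, lung",Chemotherapy (cyclophosphamide/methotrexate/5FU)
4,55,54,,√,×,+,Local disease,Chemotherapy (adriamycin/cyclophosphamide (neoadjuvant))
5,53,49,55,√,×,−,"Bone, liver",Avastin
6,40,33,41,√,×,−,"Bone, liver",Avastin and Chemotherapy (cisplatin/gemzar)
7,33,33,,√,×,+,Local disease,Targeted therapy for HER2 and Chemotherapy (navalbine (neaoadjuvant))
8,64,54,66,√,×,−,"Bone, liver",Chemotherapy (carboplatin/gemzar)
9,38,32,39,√,×,+,"Bone, lung",Targeted therapy for HER2
10,37,36,,√,×,+,Brain,Targeted therapy for HER2
11,62,46,64,√,×,−,"Liver, bone",Chemotherapy (carboplatin/gemzar)
12,84,76,,√,×,+,Local disease,Targeted therapy for HER2 and Chemotherapy (navalbine (neaoadjuvant))
13,54,36,56,√,×,−,"Bone, lung, liver",Chemotherapy (cisplatin/leucovorin/5FU)
14,58,58,,√,×,+,,Targeted therapy for HER2
15,71,69,72,√,×,−,"Lung, liver, bone",Hormonal
16,53,53,,√,×,−,,Chemotherapy (taxol (adjuvant))
17,55,49,,√,×,−,"Lung, bone",Avastin and Chemotherapy (navalbine)
18,85,80,85,√,×,−,"Liver, bone, lung",Chemotherapy (carboplatin)
19,49,48,,√,×,+,,Targeted therapy for HER2
20,35,35,,√,×,−,Local disease,Chemotherapy (taxol (neoadjuvant))
21,67,64,68,×,√,−,"Brain, bone, lung",Chemotherapy (carboplatin + taxol)
22,47,42,47,√,×,−,"Bone, liver",Chemotherapy (carboplatin/gemzar)
23,46,45,,√,×,+,,Targeted therapy for HER2
24,54,41,55,√,×,−,Bone,Hormonal and Palbocyclib
25,51,51,52,√,×,−,Bone,Hormonal and Palbocyclib
26,35,29,36,√,×,−,"Liver, bone, adrenal gland",Hormonal and Afinitor
27,62,62,,×,√,−,,Chemotherapy (taxol (adjuvant))
28,39,39,40,√,×,−,Bone,Hormonal and Palbocyclib
29,58,52,59,√,×,−,Bone,Chemotherapy (taxol)
30,56,43,57,√,×,−,"Liver, bone",Hormonal and Afinitor
31,52,52,53,√,×,−,"Bone, liver",Chemotherapy (xeloda)
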