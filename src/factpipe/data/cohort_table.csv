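patient_id,cancer_type,mta,treatment_basis,basis_alteration,gene,protein_change,variant_class,reporter_pathway,active,pfs_months,event
1,Head & Neck cancer,erlotinib,amplification,EGFR amplification,MET,R988C,VUS,ERK2,True,3.7,True
2,Head & Neck cancer,sorafenib,assayed_variant,,PIK3CA,E545K,known,FOXO1,True,1.3,True
2,Head & Neck cancer,sorafenib,assayed_variant,,PDGFRA,L655W,VUS,ERK2,False,1.3,True
3,Lung cancer,sorafenib,assayed_variant,,FLT3,M665T,VUS,STAT3,True,5.9,True
4,Lung cancer,imatinib,assayed_variant,,KIT,D572G,VUS,ERK2,True,8.4,True
5,Colorectal cancer,vemurafenib,assayed_variant,,BRAF,V600E,known,ERK2,True,5.6,True
6,Ovarian cancer,imatinib,assayed_variant,,KIT,V852I,VUS,ERK2,False,3.7,True
7,Hepatocellular carcinoma,imatinib,assayed_variant,,KIT,M722V,VUS,ERK2,False,1.5,True
8,Neuroendocrine cancer,lapatinib + trastuzumab,assayed_variant,,ERBB2,T862A,known,ERK2,True,1.1,True
8,Neuroendocrine cancer,lapatinib + trastuzumab,assayed_variant,,KRAS,G12S,known,ERK2,True,1.1,True
9,Lung cancer,lapatinib + trastuzumab,amplification,ERBB2 amplification,EGFR,E746_T751>A,known,ERK2,True,2.0,True
10,Colorectal cancer,lapatinib + trastuzumab,assayed_variant,,ERBB2,S792F,VUS,ERK2,False,1.9,True
10,Colorectal cancer,lapatinib + trastuzumab,assayed_variant,,KRAS,G12D,known,ERK2,True,1.9,True
11,Colorectal cancer,sorafenib,amplification,PDGFRA amplification,PIK3CA,E545K,known,FOXO1,True,2.3,True
12,Melanoma,imatinib,assayed_variant,,KIT,P838S,VUS,ERK2,False,1.6,True
12,Melanoma,imatinib,assayed_variant,,NRAS,Q61L,known,ERK2,True,1.6,True
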