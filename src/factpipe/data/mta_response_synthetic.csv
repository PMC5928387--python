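combo_id,drug,untreated_activity,dose_index,activity
FLT3:M665T,sorafenib,95.0,1,90.0
FLT3:M665T,sorafenib,95.0,2,78.0
FLT3:M665T,sorafenib,95.0,3,55.0
FLT3:M665T,sorafenib,95.0,4,30.0
FLT3:M665T,sorafenib,95.0,5,12.0
FLT3:M665T,sorafenib,95.0,6,4.0
KIT:D572G,imatinib,88.0,1,85.0
KIT:D572G,imatinib,88.0,2,70.0
KIT:D572G,imatinib,88.0,3,48.0
KIT:D572G,imatinib,88.0,4,25.0
KIT:D572G,imatinib,88.0,5,10.0
KIT:D572G,imatinib,88.0,6,3.0
BRAF:V600E,vemurafenib,100.0,1,97.0
BRAF:V600E,vemurafenib,100.0,2,85.0
BRAF:V600E,vemurafenib,100.0,3,60.0
BRAF:V600E,vemurafenib,100.0,4,35.0
BRAF:V600E,vemurafenib,100.0,5,14.0
BRAF:V600E,vemurafenib,100.0,6,5.0
ERBB2:T862A+KRAS:G12S,lapatinib,92.0,1,90.0
ERBB2:T862A+KRAS:G12S,lapatinib,92.0,2,88.0
ERBB2:T862A+KRAS:G12S,lapatinib,92.0,3,85.0
ERBB2:T862A+KRAS:G12S,lapatinib,92.0,4,82.0
ERBB2:T862A+KRAS:G12S,lapatinib,92.0,5,80.0
ERBB2:T862A+KRAS:G12S,lapatinib,92.0,6,78.0
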