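drug,gene
sorafenib,FLT3
sorafenib,PDGFRA
sorafenib,KIT
sorafenib,RAF1
sorafenib,BRAF
imatinib,KIT
imatinib,PDGFRA
vemurafenib,BRAF
lapatinib,ERBB2
lapatinib,EGFR
trastuzumab,ERBB2
erlotinib,EGFR
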