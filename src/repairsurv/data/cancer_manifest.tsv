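cancer_code	cancer_name	has_stage
aml	Acute myelogenous leukemia	0
bladder	Bladder	0
brainlgg	Low grade gliomas	0
gbm	Glioblastoma multiforme	0
headneck	Head and neck	0
sarcoma	Sarcoma	0
breast	Breast	1
cervical	Cervical	1
colorectal	Colorectal	1
liver	Liver	1
lung	Lung	1
lungsc	Lung squamous cell	1
melanoma	Melanoma	1
ovarian	Ovarian	1
rcc	Renal clear cell	1
rpc	Renal papillary	1
stomach	Stomach	1
uterine	Uterine	1
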