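vocabulary	code	preferred_name	synonyms
RxNorm	56946	Paclitaxel	taxol
RxNorm	194000	Capecitabine
RxNorm	61381	olanzapine	Zyprexa
SNOMED-CT	26929004	Alzheimer Disease	Alzheimer's disease;Alzheimers disease
SNOMED-CT	20000101	Urinary bladder neoplasms	Bladder cancer;Urinary Bladder Neoplasms
SNOMED-CT	20000102	Arthritis, Rheumatoid	Rheumatoid arthritis
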