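Entity1_id	Entity1_name	Entity1_type	Entity2_id	Entity2_name	Entity2_type	PMIDs
PA443512	Urinary bladder neoplasms	Disease	rs762551	rs762551	Variant location	18798002
rs762551	rs762551	Variant location	PA443434	Arthritis, Rheumatoid	Disease	18496682
PA443434	Arthritis, Rheumatoid	Disease	PA27093	CYP1A2	Gene	18496682;19581389
PA27093	CYP1A2	Gene	PA450688	olanzapine	Drug	19636338;21519338
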