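# Drug-label safety changes announced by the UK regulator in 2009 for three
# monoclonal antibodies, as (DrugBank-style id, MedDRA-style id) pairs.
# Rituximab -> progressive multifocal leukoencephalopathy
DB00073	MedDRA:10036807
# Efalizumab -> progressive multifocal leukoencephalopathy
DB00095	MedDRA:10036807
# Natalizumab -> hypersensitivity
DB00108	MedDRA:10020751
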