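# Synthetic stand-in for a drug-label side-effect reference (SIDER-style):
# adverse effects already on the leaflets of the three drugs of interest.
# Deliberately lacks the pairs later added by the 2009 label changes.
# Rituximab: infusion-related reaction, neutropenia
DB00073	MedDRA:10022086
DB00073	MedDRA:10029354
# Efalizumab: headache, thrombocytopenia
DB00095	MedDRA:10019211
DB00095	MedDRA:10043554
# Natalizumab: fatigue, urinary tract infection
DB00108	MedDRA:10016256
DB00108	MedDRA:10046571
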