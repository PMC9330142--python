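variant	score_name	value
m.11778G>A	APOGEE	0.52
m.11778G>A	MToolBox	0.61
m.14258G>A	APOGEE	0.47
m.14484T>C	APOGEE	0.44
m.14582A>G	APOGEE	0.39
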