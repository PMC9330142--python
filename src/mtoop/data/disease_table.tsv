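variant	disease
m.11778G>A	LHON
m.14484T>C	LHON
m.3460G>A	LHON
m.1555A>G	Deafness
m.3243A>G	MELAS
m.8344A>G	MERRF
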