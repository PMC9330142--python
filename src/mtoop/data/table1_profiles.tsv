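sample_id	cohort	group	variant	heteroplasmy	doubt_flag	haplogroup	haplogroup_quality
AFR_CTRL_L3e2b1a2	control	discovery	m.769G>A	0.99	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.1018G>A	0.99	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.2352T>C	0.99	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.4158A>G	0.99	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.6150G>A	0.99	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.9377A>G	0.99	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.11778G>A	0.97	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.15946C>T	0.99	0	L3e2b1a2	0.98
AFR_CTRL_L3e2b1a2	control	discovery	m.16041A>G	0.99	0	L3e2b1a2	0.98
EUR_CASE_U5a1a1	case	replication	m.1700T>C	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.3197T>C	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.5495T>C	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.8701A>G	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.9540T>C	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.11467A>G	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.11778G>A	0.97	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.12308A>G	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.12705C>T	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.14793A>G	0.99	0	U5a1a1	0.98
EUR_CASE_U5a1a1	case	replication	m.15218A>G	0.99	0	U5a1a1	0.98
EUR_CTRL_H3c2b1	control	replication	m.2259C>T	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.2581A>G	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.6253T>C	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.6776T>C	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.9540T>C	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.9947G>A	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.12705C>T	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.13759G>A	0.99	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.14484T>C	0.97	0	H3c2b1	0.98
EUR_CTRL_H3c2b1	control	replication	m.16093T>C	0.99	0	H3c2b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.1555A>G	0.97	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.4646T>C	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.5999T>C	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.7705T>C	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.8701A>G	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.9540T>C	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.11467A>G	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.12308A>G	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.12705C>T	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.13020T>C	0.99	0	U4b1b1	0.98
EUR_CTRL_U4b1b1	control	replication	m.15693T>C	0.99	0	U4b1b1	0.98
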