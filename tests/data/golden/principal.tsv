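gene_id	transcript_id
G000	G000.T0
G002	G002.T0
G003	G003.T0
G004	G004.T0
G007	G007.T0
G008	G008.T0
G010	G010.T0
G012	G012.T1
G013	G013.T0
G014	G014.T1
G017	G017.T0
G018	G018.T0
G019	G019.T1
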