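ligand	receptor	mean	sd
AM-2	MMP-2	413.1	76.3
AM-2	MMP-3	534.6	94.2
AM-5	MMP-2	431.3	69.9
AM-5	MMP-3	567.4	84.9
AM-6	MMP-2	440.1	95.6
AM-6	MMP-3	697.1	52.1
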