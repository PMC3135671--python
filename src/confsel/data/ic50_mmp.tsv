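ligand	receptor	ic50
AM-2	MMP-2	9.3
AM-2	MMP-3	0.24
AM-5	MMP-2	0.61
AM-5	MMP-3	0.01
AM-6	MMP-2	>50
AM-6	MMP-3	0.019
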