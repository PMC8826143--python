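bijwerking	general_adr	0.6
bijwerkingen	general_adr	0.6
allergie	general_adr	0.6
allergisch	general_adr	0.6
intolerantie	general_adr	0.6
overgevoeligheid	general_adr	0.6
overgevoelig	general_adr	0.6
reactie	general_adr	0.6
contraindicatie	general_adr	0.6
onverdraagzaamheid	general_adr	0.6
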