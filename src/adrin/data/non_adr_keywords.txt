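verhoogd
verhoog
verhogen
opgehoogd
ophogen
verlaagd
verlaag
verlagen
verdubbeld
verdubbel
afgebouwd
afbouwen
gehalveerd
halveren
uitgebreid
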