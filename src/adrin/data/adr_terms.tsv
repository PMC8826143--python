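duizelig	adr	0.6
duizeligheid	adr	0.6
misselijk	adr	0.6
braken	adr	0.6
hoesten	adr	0.6
prikkelhoest	adr	0.6
oedeem	adr	0.6
hoofdpijn	adr	0.6
migraine	adr	0.6
moeheid	adr	0.6
vermoeidheid	adr	0.6
spierpijn	adr	0.6
spierkramp	adr	0.6
jeuk	adr	0.6
huiduitslag	adr	0.6
diarree	adr	0.6
obstipatie	adr	0.6
hartkloppingen	adr	0.6
kortademigheid	adr	0.6
benauwdheid	adr	0.6
flauwvallen	adr	0.6
sufheid	adr	0.6
slapeloosheid	adr	0.6
nachtmerries	adr	0.6
smaakverandering	adr	0.6
impotentie	adr	0.6
depressie	adr	0.6
tintelingen	adr	0.6
spierzwakte	adr	0.6
haaruitval	adr	0.6
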