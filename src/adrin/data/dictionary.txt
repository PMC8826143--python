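duizelig
duizeligheid
duizellig
draaierig
misselijk
misselijkheid
miselijk
braken
overgeven
hoesten
hoessten
droge hoest
kriebelhoest
prikkelhoest
oedeem
odeem
enkeloedeem
dikke enkels
hoofdpijn
hoofdpin
migraine
moeheid
moeiheid
vermoeidheid
spierpijn
spierkramp
jeuk
huiduitslag
galbulten
diarree
obstipatie
verstopping
hartkloppingen
palpitaties
kortademigheid
benauwdheid
dyspnoe
flauwvallen
syncope
collaps
sufheid
slaperigheid
slapeloosheid
nachtmerries
smaakverandering
droge mond
impotentie
erectiestoornis
depressie
somberheid
pijn op de borst
druk op de borst
maagpijn
maagklachten
buikpijn
opgeblazen gevoel
tintelingen
koude handen
koude voeten
spierzwakte
gewrichtspijn
haaruitval
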