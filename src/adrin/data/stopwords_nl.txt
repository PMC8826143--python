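de
het
een
en
van
op
in
met
voor
is
te
dat
die
aan
bij
naar
uit
over
als
maar
om
ook
al
dan
dus
nog
geen
niet
wel
wordt
werd
zijn
was
heeft
had
kan
kon
zal
zou
er
hier
daar
deze
dit
na
tot
door
onder
tussen
ik
hij
zij
we
u
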