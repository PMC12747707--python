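# Frozen Dutch stopword list (function words, pronouns, auxiliaries, units).
# Versioned with the package so preprocessing is reproducible regardless of
# upstream library changes. One token per line; lines starting with '#' ignored.
aan
al
alles
als
altijd
andere
ben
bij
bijna
daar
dan
dat
de
der
deze
die
dit
doch
doen
door
dus
een
eens
en
er
ge
geen
geweest
haar
heb
hebben
heeft
hem
het
hier
hij
hoe
hun
iemand
iets
ik
in
is
ja
je
kan
keer
kon
kunnen
maar
me
meer
men
met
mij
mijn
minuut
moet
na
naar
niet
niets
nog
nooit
nu
of
om
omdat
onder
ons
ook
op
over
reeds
te
tegen
toch
toen
tot
u
uit
uur
uw
van
veel
voor
want
waren
was
wat
we
wel
werd
wezen
wie
wil
worden
wordt
zal
ze
zelf
zich
zij
zijn
zo
zonder
zou
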