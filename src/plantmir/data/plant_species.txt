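# Three-letter species prefixes of plant (Viridiplantae) entries in the
# miRBase mature registry. One prefix per line; lines starting with '#'
# are comments. Override with your own file if your registry release
# differs.
aau
ahy
aly
aqc
ata
ath
atr
bcy
bdi
bgy
bna
bol
bra
ccl
cca
cme
cpa
cre
crt
csi
cst
ctr
dpr
egr
esi
far
fve
gar
ghb
ghr
gma
gra
gso
han
hbr
hci
hex
hpa
htu
hvu
lja
lus
mdm
mes
mtr
nta
nto
osa
pab
pde
peu
pgi
pin
ppe
ppt
pra
pta
ptc
pvu
rco
rgl
sbi
sly
smo
sof
ssl
ssp
stu
tae
tcc
vca
vun
vvi
zma
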