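# token	tag  (E noun, A state adjective, R adverb, D determiner,
#              S preposition, C conjunction, U unit, V verb)
alto	E
altura	E
ancho	E
arbusto	E
arilo	E
base	E
brácteas	E
corola	E
corteza	E
cáliz	E
diámetro	E
domacios	E
envés	E
espinas	E
estambres	E
estigma	E
estípulas	E
flor	E
flores	E
fruto	E
frutos	E
glándulas	E
grosor	E
grupo	E
grupos	E
haz	E
hoja	E
hojas	E
inflorescencia	E
inflorescencias	E
largo	E
longitud	E
lámina	E
láminas	E
margen	E
márgenes	E
nervadura	E
nueces	E
nuez	E
ovario	E
panícula	E
panículas	E
parte	E
partes	E
pecíolo	E
pecíolos	E
pelos	E
planta	E
puntuaciones	E
pétalos	E
racimo	E
racimos	E
rama	E
ramas	E
ramitas	E
semilla	E
semillas	E
superficie	E
sépalos	E
tallo	E
tallos	E
tricomas	E
vena	E
venas	E
yemas	E
ápice	E
árbol	E
acuminada	A
acuminadas	A
acuminado	A
acuminados	A
aguda	A
agudas	A
agudo	A
agudos	A
alterna	A
alternas	A
alterno	A
alternos	A
amarillenta	A
amarillentas	A
amarillento	A
amarillentos	A
amarilla	A
amarillas	A
amarillo	A
amarillos	A
anaranjada	A
anaranjadas	A
anaranjado	A
anaranjados	A
aserrada	A
aserradas	A
aserrado	A
aserrados	A
bipinnada	A
bipinnadas	A
bipinnado	A
bipinnados	A
blanca	A
blancas	A
blanco	A
blancos	A
caduca	A
caducas	A
caduco	A
caducos	A
cartácea	A
cartáceas	A
cartáceo	A
cartáceos	A
caudada	A
caudadas	A
caudado	A
caudados	A
compuesta	A
compuestas	A
compuesto	A
compuestos	A
cordada	A
cordadas	A
cordado	A
cordados	A
coriácea	A
coriáceas	A
coriáceo	A
coriáceos	A
crenada	A
crenadas	A
crenado	A
crenados	A
decidua	A
deciduas	A
deciduo	A
deciduos	A
dentada	A
dentadas	A
dentado	A
dentados	A
dentado-mucronada	A
dentado-mucronadas	A
dentado-mucronado	A
dentado-mucronados	A
dispersa	A
dispersas	A
disperso	A
dispersos	A
elíptica	A
elípticas	A
elíptico	A
elípticos	A
entera	A
enteras	A
entero	A
enteros	A
espiralada	A
espiraladas	A
espiralado	A
espiralados	A
falcada	A
falcadas	A
falcado	A
falcados	A
fasciculada	A
fasciculadas	A
fasciculado	A
fasciculados	A
glabra	A
glabras	A
glabro	A
glabros	A
grisácea	A
grisáceas	A
grisáceo	A
grisáceos	A
hirsuta	A
hirsutas	A
hirsuto	A
hirsutos	A
lanceolada	A
lanceoladas	A
lanceolado	A
lanceolados	A
lisa	A
lisas	A
liso	A
lisos	A
lobulada	A
lobuladas	A
lobulado	A
lobulados	A
lustrosa	A
lustrosas	A
lustroso	A
lustrosos	A
membranácea	A
membranáceas	A
membranáceo	A
membranáceos	A
morada	A
moradas	A
morado	A
morados	A
negra	A
negras	A
negro	A
negros	A
oblonga	A
oblongas	A
oblongo	A
oblongos	A
obovada	A
obovadas	A
obovado	A
obovados	A
obtusa	A
obtusas	A
obtuso	A
obtusos	A
opuesta	A
opuestas	A
opuesto	A
opuestos	A
ovada	A
ovadas	A
ovado	A
ovados	A
parda	A
pardas	A
pardo	A
pardos	A
pinnada	A
pinnadas	A
pinnado	A
pinnados	A
pálida	A
pálidas	A
pálido	A
pálidos	A
redondeada	A
redondeadas	A
redondeado	A
redondeados	A
revoluta	A
revolutas	A
revoluto	A
revolutos	A
rojiza	A
rojizas	A
rojizo	A
rojizos	A
roja	A
rojas	A
rojo	A
rojos	A
rugosa	A
rugosas	A
rugoso	A
rugosos	A
serrada	A
serradas	A
serrado	A
serrados	A
subcordada	A
subcordadas	A
subcordado	A
subcordados	A
subentera	A
subenteras	A
subentero	A
subenteros	A
tomentosa	A
tomentosas	A
tomentoso	A
tomentosos	A
tomentulosa	A
tomentulosas	A
tomentuloso	A
tomentulosos	A
verdosa	A
verdosas	A
verdoso	A
verdosos	A
verticilada	A
verticiladas	A
verticilado	A
verticilados	A
apical	A
apicales	A
axilar	A
axilares	A
basal	A
basales	A
brillante	A
brillantes	A
central	A
centrales	A
crema	A
distal	A
distales	A
glabrescente	A
glabrescentes	A
lateral	A
laterales	A
linear	A
lineares	A
orbicular	A
orbiculares	A
persistente	A
persistentes	A
pubescente	A
pubescentes	A
simple	A
simples	A
terminal	A
terminales	A
verde	A
verdes	A
levemente	R
finamente	R
densamente	R
cortamente	R
esparcidamente	R
usualmente	R
raramente	R
espaciadamente	R
ligeramente	R
escasamente	R
comúnmente	R
generalmente	R
marcadamente	R
ampliamente	R
muy	R
casi	R
algo	R
a veces	R
rara vez	R
a menudo	R
por lo general	R
el	D
la	D
los	D
las	D
un	D
una	D
unos	D
unas	D
lo	D
varias	D
varios	D
algunas	D
algunos	D
pocas	D
pocos	D
muchas	D
muchos	D
numerosas	D
numerosos	D
todas	D
todos	D
ambas	D
ambos	D
a	S
de	S
del	S
al	S
en	S
por	S
con	S
sin	S
sobre	S
entre	S
hacia	S
desde	S
hasta	S
bajo	S
ante	S
según	S
a lo largo de	S
cerca de	S
por encima de	S
por debajo de	S
y	C
o	C
u	C
e	C
ni	C
que	C
cm	U
mm	U
m	U
dm	U
km	U
salen	V
nacen	V
crecen	V
presentan	V
miden	V
sale	V
nace	V
crece	V
presenta	V
mide	V
cubren	V
llegan	V
alcanzan	V
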