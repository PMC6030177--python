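# spanish	english
acuminada	acuminate
acuminadas	acuminate
acuminado	acuminate
acuminados	acuminate
aguda	acute
agudas	acute
agudo	acute
agudos	acute
alterna	alternate
alternas	alternate
alterno	alternate
alternos	alternate
alto	height
altura	height
amarilla	yellow
amarillas	yellow
amarillenta	yellowish
amarillentas	yellowish
amarillento	yellowish
amarillentos	yellowish
amarillo	yellow
amarillos	yellow
anaranjada	orange
anaranjadas	orange
anaranjado	orange
anaranjados	orange
ancho	width
apical	apical
apicales	apical
arbusto	shrub
arilo	aryl
aserrada	serrate
aserradas	serrate
aserrado	serrate
aserrados	serrate
axilar	axillary
axilares	axillary
basal	basal
basales	basal
base	base
bipinnada	bipinnate
bipinnadas	bipinnate
bipinnado	bipinnate
bipinnados	bipinnate
blanca	white
blancas	white
blanco	white
blancos	white
brillante	shiny
brillantes	shiny
brácteas	bracts
caduca	deciduous
caducas	deciduous
caduco	deciduous
caducos	deciduous
cartácea	chartaceous
cartáceas	chartaceous
cartáceo	chartaceous
cartáceos	chartaceous
caudada	caudate
caudadas	caudate
caudado	caudate
caudados	caudate
central	central
centrales	central
compuesta	compound
compuestas	compound
compuesto	compound
compuestos	compound
cordada	cordate
cordadas	cordate
cordado	cordate
cordados	cordate
coriácea	coriaceous
coriáceas	coriaceous
coriáceo	coriaceous
coriáceos	coriaceous
corola	corolla
corteza	bark
crema	cream
crenada	crenate
crenadas	crenate
crenado	crenate
crenados	crenate
cáliz	calyx
decidua	deciduous
deciduas	deciduous
deciduo	deciduous
deciduos	deciduous
dentada	dentate
dentadas	dentate
dentado	dentate
dentado-mucronada	dentate-mucronate
dentado-mucronadas	dentate-mucronate
dentado-mucronado	dentate-mucronate
dentado-mucronados	dentate-mucronate
dentados	dentate
dispersa	scattered
dispersas	scattered
disperso	scattered
dispersos	scattered
distal	distal
distales	distal
diámetro	diameter
domacios	domatia
elíptica	elliptic
elípticas	elliptic
elíptico	elliptic
elípticos	elliptic
entera	entire
enteras	entire
entero	entire
enteros	entire
envés	underside
espinas	spines
espiralada	spiral
espiraladas	spiral
espiralado	spiral
espiralados	spiral
estambres	stamens
estigma	stigma
estípulas	stipules
falcada	falcate
falcadas	falcate
falcado	falcate
falcados	falcate
fasciculada	fasciculate
fasciculadas	fasciculate
fasciculado	fasciculate
fasciculados	fasciculate
flor	flower
flores	flowers
fruto	fruit
frutos	fruits
glabra	glabrous
glabras	glabrous
glabrescente	glabrescent
glabrescentes	glabrescent
glabro	glabrous
glabros	glabrous
glándulas	glands
grisácea	greyish
grisáceas	greyish
grisáceo	greyish
grisáceos	greyish
grosor	thickness
grupo	group
grupos	groups
haz	upperside
hirsuta	hirsute
hirsutas	hirsute
hirsuto	hirsute
hirsutos	hirsute
hoja	leaf
hojas	leaves
inflorescencia	inflorescence
inflorescencias	inflorescences
lanceolada	lanceolate
lanceoladas	lanceolate
lanceolado	lanceolate
lanceolados	lanceolate
largo	length
lateral	lateral
laterales	lateral
linear	linear
lineares	linear
lisa	smooth
lisas	smooth
liso	smooth
lisos	smooth
lobulada	lobed
lobuladas	lobed
lobulado	lobed
lobulados	lobed
longitud	length
lustrosa	lustrous
lustrosas	lustrous
lustroso	lustrous
lustrosos	lustrous
lámina	blade
láminas	blades
margen	margin
membranácea	membranaceous
membranáceas	membranaceous
membranáceo	membranaceous
membranáceos	membranaceous
morada	purple
moradas	purple
morado	purple
morados	purple
márgenes	margins
negra	black
negras	black
negro	black
negros	black
nervadura	venation
nueces	nuts
nuez	nut
oblonga	oblong
oblongas	oblong
oblongo	oblong
oblongos	oblong
obovada	obovate
obovadas	obovate
obovado	obovate
obovados	obovate
obtusa	obtuse
obtusas	obtuse
obtuso	obtuse
obtusos	obtuse
opuesta	opposite
opuestas	opposite
opuesto	opposite
opuestos	opposite
orbicular	orbicular
orbiculares	orbicular
ovada	ovate
ovadas	ovate
ovado	ovate
ovados	ovate
ovario	ovary
panícula	panicle
panículas	panicles
parda	brown
pardas	brown
pardo	brown
pardos	brown
parte	part
partes	parts
pecíolo	petiole
pecíolos	petioles
pelos	hairs
persistente	persistent
persistentes	persistent
pinnada	pinnate
pinnadas	pinnate
pinnado	pinnate
pinnados	pinnate
planta	plant
pubescente	pubescent
pubescentes	pubescent
puntuaciones	dots
pálida	pale
pálidas	pale
pálido	pale
pálidos	pale
pétalos	petals
racimo	cluster
racimos	clusters
rama	branch
ramas	branches
ramitas	twigs
redondeada	rounded
redondeadas	rounded
redondeado	rounded
redondeados	rounded
revoluta	revolute
revolutas	revolute
revoluto	revolute
revolutos	revolute
roja	red
rojas	red
rojiza	reddish
rojizas	reddish
rojizo	reddish
rojizos	reddish
rojo	red
rojos	red
rugosa	rugose
rugosas	rugose
rugoso	rugose
rugosos	rugose
semilla	seed
semillas	seeds
serrada	serrate
serradas	serrate
serrado	serrate
serrados	serrate
simple	simple
simples	simple
subcordada	subcordate
subcordadas	subcordate
subcordado	subcordate
subcordados	subcordate
subentera	subentire
subenteras	subentire
subentero	subentire
subenteros	subentire
superficie	surface
sépalos	sepals
tallo	stem
tallos	stems
terminal	terminal
terminales	terminal
tomentosa	tomentose
tomentosas	tomentose
tomentoso	tomentose
tomentosos	tomentose
tomentulosa	tomentulose
tomentulosas	tomentulose
tomentuloso	tomentulose
tomentulosos	tomentulose
tricomas	trichomes
vena	vein
venas	veins
verde	green
verdes	green
verdosa	greenish
verdosas	greenish
verdoso	greenish
verdosos	greenish
verticilada	whorled
verticiladas	whorled
verticilado	whorled
verticilados	whorled
yemas	buds
ápice	apex
árbol	tree
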