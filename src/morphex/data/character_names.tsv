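# state_en	character_name
acuminate	shape
acute	shape
alternate	arrangement
apical	position
axillary	position
basal	position
bipinnate	architecture
black	colouration
brown	colouration
caudate	shape
central	position
chartaceous	texture
compound	architecture
cordate	shape
coriaceous	texture
cream	colouration
crenate	architecture
deciduous	duration
dentate	architecture
dentate-mucronate	architecture
distal	position
elliptic	arrangement
elliptic	shape
entire	architecture
falcate	shape
fasciculate	arrangement
glabrescent	pubescence
glabrous	pubescence
green	colouration
greenish	colouration
greyish	colouration
hirsute	pubescence
lanceolate	shape
lateral	position
linear	shape
lobed	architecture
lustrous	texture
membranaceous	texture
oblong	shape
obovate	shape
obtuse	shape
opposite	arrangement
orange	colouration
orbicular	shape
ovate	shape
pale	colouration
persistent	duration
pinnate	architecture
pubescent	pubescence
purple	colouration
red	colouration
reddish	colouration
revolute	shape
rounded	shape
rugose	texture
scattered	arrangement
serrate	architecture
shiny	texture
simple	architecture
smooth	texture
spiral	arrangement
subcordate	shape
subentire	architecture
terminal	position
tomentose	pubescence
tomentulose	pubescence
white	colouration
whorled	arrangement
yellow	colouration
yellowish	colouration
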