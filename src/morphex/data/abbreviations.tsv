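# abbreviation (with period)	expansion (no periods)
aprox.	aproximadamente
diám.	diámetro
long.	longitud
alt.	altura
fls.	flores
frs.	frutos
infl.	inflorescencia
ca.	aproximadamente
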