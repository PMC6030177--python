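# token	gender	number  (overrides the suffix heuristic)
base	feminine	singular
ápice	masculine	singular
margen	masculine	singular
envés	masculine	singular
haz	masculine	singular
tallo	masculine	singular
parte	feminine	singular
partes	feminine	plural
tricomas	masculine	plural
crema	unknown	singular
flor	feminine	singular
flores	feminine	plural
nuez	feminine	singular
nueces	feminine	plural
cáliz	masculine	singular
superficie	feminine	singular
estigma	masculine	singular
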