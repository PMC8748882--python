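phoneme	representation	group
p	articulatory	labial
p	phonetic	plosive
b	articulatory	labial
b	phonetic	plosive
t	articulatory	coronal
t	phonetic	plosive
d	articulatory	coronal
d	phonetic	plosive
k	articulatory	dorsal
k	phonetic	plosive
ɡ	articulatory	dorsal
ɡ	phonetic	plosive
s	articulatory	coronal
s	phonetic	fricative
z	articulatory	coronal
z	phonetic	fricative
f	articulatory	labial
f	phonetic	fricative
v	articulatory	labial
v	phonetic	fricative
θ	articulatory	coronal
θ	phonetic	fricative
ð	articulatory	coronal
ð	phonetic	fricative
ʃ	articulatory	coronal
ʃ	phonetic	fricative
ʒ	articulatory	coronal
ʒ	phonetic	fricative
ç	articulatory	dorsal
ç	phonetic	fricative
x	articulatory	dorsal
x	phonetic	fricative
ʁ	articulatory	dorsal
ʁ	phonetic	fricative
m	articulatory	labial
m	phonetic	nasal
n	articulatory	coronal
n	phonetic	nasal
ŋ	articulatory	dorsal
ŋ	phonetic	nasal
l	articulatory	coronal
l	phonetic	approximant
ɹ	articulatory	coronal
ɹ	phonetic	approximant
j	articulatory	dorsal
j	phonetic	approximant
w	articulatory	labial
w	articulatory	dorsal
w	phonetic	approximant
i	vocalic	high-front
ɪ	vocalic	high-front
y	vocalic	high-front
e	vocalic	high-front
u	vocalic	high-back
ʊ	vocalic	high-back
o	vocalic	high-back
ɛ	vocalic	low-front
æ	vocalic	low-front
a	vocalic	low-front
ɑ	vocalic	low-back
ɔ	vocalic	low-back
ə	vocalic	central
œ	vocalic	central
ø	vocalic	central
ɐ	vocalic	central
ɑ̃	vocalic	low-back
ɔ̃	vocalic	low-back
ɛ̃	vocalic	low-front
œ̃	vocalic	central
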