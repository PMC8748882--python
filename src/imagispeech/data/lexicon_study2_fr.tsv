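item	ipa	category
pousser	puse	concrete_verb
manger	mɑ̃ʒe	concrete_verb
courir	kuʁiʁ	concrete_verb
pallier	palje	abstract_verb
penser	pɑ̃se	abstract_verb
élire	eliʁ	abstract_verb
enfant	ɑ̃fɑ̃	concrete_noun
lumière	lymjɛʁ	concrete_noun
girafe	ʒiʁaf	concrete_noun
état	eta	abstract_noun
mensonge	mɑ̃sɔ̃ʒ	abstract_noun
bonheur	bɔnœʁ	abstract_noun
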