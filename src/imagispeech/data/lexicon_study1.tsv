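item	ipa
spoon	spun
cowboys	kaʊbɔɪz
battlefield	bætəlfild
swimming	swɪmɪŋ
python	paɪθən
telephone	tɛləfoʊn
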