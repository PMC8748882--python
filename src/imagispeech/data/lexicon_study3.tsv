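item	ipa
ba	ba
da	da
ga	ɡa
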