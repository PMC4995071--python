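increases	increas
increases	induc
increases	enhanc
increases	upregulat
increases	up-regulat
increases	activat
increases	stimulat
increases	promot
increases	elevat
increases	augment
increases	potentiat
increases	rais
decreases	decreas
decreases	inhibit
decreases	suppress
decreases	reduc
decreases	downregulat
decreases	down-regulat
decreases	block
decreases	attenuat
decreases	abolish
decreases	repress
decreases	impair
decreases	diminish
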