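population	locality	sample_size
KW	West coast of the Korean Peninsula	17
KS	Nan Hai along the shore of Korea	21
RS	Rushan Bay of the Yellow Sea	17
HZ	Haizhou Bay of the Yellow Sea	18
LD	Liaodong Bay of the Bohai Sea	20
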