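id	target	sequence	orientation
Cel48_490F_I	GH48	T[I]ATGGTTGAAGCTCCDGAYTAYGG	forward
Cel48_920R_I	GH48	CCAAA[I]CCRTACCAGTTRTCAACRTC	reverse
F919mod	16S	GAATTGACGGGGRYCCGCACAAG	forward
R1378mod	16S	CGGTGTGTACAAGRCCCGRGAACG	reverse
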