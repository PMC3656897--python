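name	residues	fatty_acid	lactone_donor
xantholysin A	Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Ile	C10:0-3OH	7
xantholysin B	Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Val	C10:0-3OH	7
xantholysin C	Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Ile	C12:1(5c)-3OH	7
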