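g01	activation	g02
g01	activation	g03
g02	activation	g03
g02	activation	g05
g03	activation	g04
g05	activation	g06
g06	activation	g04
g06	activation	g07
g04	activation	g07
g07	activation	g08
g07	activation	g10
g08	activation	g09
g08	activation	g14
g10	activation	g11
g11	activation	g09
g11	activation	g12
g09	activation	g12
g12	activation	g13
g13	activation	g14
g14	activation	g15
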