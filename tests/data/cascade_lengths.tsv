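gene	length
g01	1000
g02	1000
g03	500000
g04	1000
g05	1000
g06	1000
g07	2000
g08	1000
g09	1000
g10	1000
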