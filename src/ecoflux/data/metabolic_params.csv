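group,ln_i0,a,E
default,23.055,0.695,0.686
insecta,23.055,0.695,0.686
arachnida,22.800,0.565,0.665
myriapoda,22.300,0.560,0.655
crustacea,22.500,0.570,0.670
annelida,22.000,0.750,0.600
gastropoda,21.500,0.740,0.580
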