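name,code,percentage,sd
Caproic acid,C6:0,N.D.,
Capric acid,C10:0,N.D.,
Lauric acid,C12:0,N.D.,
Myristic acid,C14:0,1.72,0.01
Pentadecanoic acid,C15:0,0.55,0.04
Palmitic acid,C16:0,33.02,0.01
Margaric acid,C17:0,0.38,0.01
Steric acid,C18:0,5.63,0.02
Behenic acid,C22:0,0.23,0.02
Lignoceric acid,C24:0,0.22,0.01
Myristoleic acid,C14:1,0.34,0.03
Palmitoleic acid,C16:1,34.61,0.01
Ginkgolic acid,C17:1,0.80,0.00
Elaidic acid,C18:1n9t,2.26,0.03
Oleic acid,C18:1n9c,4.30,0.01
Erucic acid,C22:1n9,0.23,0.02
Nervonic acid,C24:1n9,0.17,0.02
gamma-Linolenic acid,C18:3n6,0.44,0.03
Linoleic acid,C18:2n6c,0.49,0.01
Arachidonic acid,C20:4n6,10.27,0.02
Eicosapentaenoic acid,C20:5n3,1.33,0.02
Dihomo-gamma-linolenic acid,C20:3n6,1.45,0.04
Eicosadienoic acid,C20:2n6,0.61,0.01
Docosahexaenoic acid,C22:6n3,0.95,0.04
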