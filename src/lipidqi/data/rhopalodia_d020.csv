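name,code,percentage,sd
Caproic acid,C6:0,0.07,0.02
Capric acid,C10:0,0.07,0.02
Lauric acid,C12:0,0.12,0.01
Myristic acid,C14:0,5.95,0.04
Pentadecanoic acid,C15:0,0.43,0.02
Palmitic acid,C16:0,31.22,0.01
Margaric acid,C17:0,0.25,0.04
Steric acid,C18:0,3.30,0.00
Behenic acid,C22:0,N.D.,
Lignoceric acid,C24:0,N.D.,
Myristoleic acid,C14:1,0.12,0.01
Palmitoleic acid,C16:1,24.67,0.02
Ginkgolic acid,C17:1,0.20,0.00
Elaidic acid,C18:1n9t,3.14,0.03
Oleic acid,C18:1n9c,7.40,0.00
Erucic acid,C22:1n9,N.D.,
Nervonic acid,C24:1n9,N.D.,
gamma-Linolenic acid,C18:3n6,1.41,0.01
Linoleic acid,C18:2n6c,12.58,0.01
Arachidonic acid,C20:4n6,5.26,0.03
Eicosapentaenoic acid,C20:5n3,2.61,0.01
Dihomo-gamma-linolenic acid,C20:3n6,0.51,0.01
Eicosadienoic acid,C20:2n6,0.49,0.01
Docosahexaenoic acid,C22:6n3,0.20,0.00
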