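species,id,accession_name,accession_number
T. aestivum,Anza,Anza,NA
T. aestivum,BW,BobWhite,NA
T. aestivum,Peri,Perico,NA
T. aestivum,TP2,UC1110,GSTR 13501
T. aestivum,TP3,OS9A,PI658243
T. aestivum,TP4,QCB 36,PI658244
T. aestivum,TP5,Opata 85,PI591776
T. aestivum,TP6,Cayuga,PI595848
T. aestivum,TP7,Caledonia,PI610188
T. aestivum,TP8,CIGM90.248,PI610750
T. aestivum,TP10,P91193,GSTR 10001
T. aestivum,TP11,P92201,GSTR 10002
T. aestivum,TP16,TAM107-R7,GSTR 11601
T. aestivum,TP17,SS550,GSTR 12501
T. aestivum,TP21,M6,PI83534
T. aestivum,TP22,Kanqueen,PI401539
T. aestivum,TP24,Avocet,PI464644
T. aestivum,TP25,Penawawa,PI495916
T. aestivum,TP27,Renan,PI564569
T. aestivum,TP28,Excalibur,PI572701
T. aestivum,TP29,McNeal,PI574642
T. aestivum,TP30,Thatcher,CItr 10003
T. aestivum,TP31,Jaypee,PI592760
T. aestivum,TP32,USG 3209,PI617055
T. aestivum,TP33,Caledonia,PI610188
T. aestivum,TP34,Cayuga,PI595848
T. durum,TP1,IDO444,GSTR 12902
T. durum,TP9,UC1113 Yr36 Gpc-B1,PI638741
T. durum,TP12,Grandin*5/ND614-A,GSTR 10401
T. durum,TP13,NY18/Clark's Cream 40-1,GSTR 10402
T. durum,TP14,Jupateco 73S,GSTR 10501
T. durum,TP15,CO940610,GSTR 10702
T. durum,TP18,Amadina,GSTR 12701
T. durum,TP19,Weebill 1,GSTR 10502
T. durum,TP20,Rugby,CItr 17284
T. durum,TP23,Avalon,PI446910
T. durum,TP26,Rio Blanco,PI531244
H. vulgare,CP1,Vada,PI280422
H. vulgare,CP2,Clipper,PI349366
H. vulgare,CP3,Ko A,PI383935
H. vulgare,CP4,Igri,PI406263
H. vulgare,CP5,Mokusekko 3,PI420938
H. vulgare,CP6,Dicktoo,CIho 5529
H. vulgare,CP7,L94,CIho 11797
H. vulgare,CP8,Fredrickson,CIho 13647
H. vulgare,CP9,Steptoe,CIho 15229
H. vulgare,CP10,Morex,Ciho 15773
H. vulgare,CP11,Lina,PI584808
H. vulgare,CP12,Apex,PI600966
H. vulgare,CP13,OWB dominant,GSHO3450
H. vulgare,CP14,OWB recessive,GSHO3451
H. vulgare,CP16,Golden Promise,PI467829
H. vulgare,CP17,Cebada Capa,PI539113
H. vulgare,CP18,Stander,PI564743
H. vulgare,CP19,Franklin,PI373729
H. vulgare,CP20,Franka,PI574293
H. vulgare,CP21,Azumamugi,J698
H. vulgare,CP22,Kanto Nakate Gold,J518
x Triticosecale,TS43,Rahum,PI422269
x Triticosecale,TS45,Zebra,PI429031
x Triticosecale,TS51,Kramer,PI476216
x Triticosecale,TS53,Currency,PI483066
x Triticosecale,TS58,Wapiti,PI511870
x Triticosecale,TS61,Yoreme Tehuacan 75,PI519876
x Triticosecale,TS67,Navojoa,PI520421
x Triticosecale,TS75,Drira,PI520478
x Triticosecale,TS78,Juanillo 95,PI520488
x Triticosecale,TS97,Armadillo 130,PI583701
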