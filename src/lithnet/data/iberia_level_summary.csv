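site_id,level_id,frame_start,frame_end,n_total,n_shared
Artusia,III,8600,8401,4,4
Artusia,V,8200,7801,2,2
Abric de la Falguera,VIII,8400,8001,2,2
Abric de la Falguera,Xa,8400,8201,1,1
Abric del Xicotó,II,7200,7001,4,2
Ángel 2,2a2,8000,7801,12,12
Atxoste,IV,8200,7601,62,60
Atxoste,IIIb2,7600,7401,22,21
Barranquet,79,7600,7401,2,2
Benàmer,I,8400,8201,32,32
Benàmer,II,7600,7401,3,2
Botiquería dels Moros,2,8600,8201,43,42
Botiquería dels Moros,4,7800,7601,16,12
Cabezo de la Cruz,Cabaña,8000,7801,8,8
Casa Corona,LM,8000,7801,12,11
Caserna de Sant Pau,IV-base,7400,7201,1,1
Castillejos,I,7400,6801,2,2
Can Sadurní,18 (IIIC),7400,7200,1,1
Cingle de Mas Cremat,VI,7800,7401,1,1
Cingle de Mas Cremat,V,7800,7601,8,8
Cingle de Mas Cremat,III,7000,6801,1,1
Costamar,NII,7000,6801,12,10
Cueva de Cocina,A1,8600,8201,57,57
Cueva de Cocina,A2,8400,8001,85,85
Cueva de Cocina,B1,8000,7601,96,96
Cueva de Cocina,B2,8000,7601,173,173
Cueva de Cocina,B3,7800,7401,20,20
Cova de l'Or,IV,7400,7001,11,10
Cova de l'Or,V,7400,7201,27,26
Cova de l'Or,VI,7400,7001,44,43
Cova de les Cendres,XI,7600,7201,3,2
Cova de les Cendres,X,7400,7001,1,0
Cova de les Cendres,IX,7200,7001,2,2
Cova de les Cendres,VIIa,7200,6801,1,1
Cova dels Trocs,53,7000,6800,2,2
Coves del Fem,103,7600,7401,4,2
Cueva de Chaves,Ib,7600,7201,38,23
Cueva de Chaves,Ia,7200,7001,6,4
Cueva de Nerja,NM10,7400,7201,5,4
Cueva de Nerja,NV2,7200,7001,1,1
Cueva del Toro,IV,7200,7001,4,4
El Abrigo de Valcervera,b,8000,7801,4,4
El Collado,I-3,8600,8401,4,4
El Esplugón,3-inf,8000,7601,47,45
Espantalobos,c,8400,8201,7,7
Forcas II,II,8000,7801,14,14
Forcas II,IV,8000,7801,26,24
La Draga,ABC,7200,6801,14,9
Les Guixeres de Vilobí,A,7600,7401,5,3
Les Guixeres de Vilobí,B,7000,6801,1,1
Mas d'Is,VIb,7600,7401,2,1
Mas Nou,III (Burial),7800,7600,2,2
Pontet,e,8200,8001,14,14
Valmayor,XI-III,7000,6801,5,4
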