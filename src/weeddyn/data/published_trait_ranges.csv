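species,field_code,min,max,n
Abutilon theophrasti,COMPHEIGHT,97,300,10
Abutilon theophrasti,COMPHYP_1,0.9,60.3,23
Abutilon theophrasti,FECUNDITY_2,2.48,3.31,2
Abutilon theophrasti,GERMBASE,6.2,6.5,2
Abutilon theophrasti,EMDEPTH_2,12,12,1
Abutilon theophrasti,EMTOT_1,1.5,1.9,3
Abutilon theophrasti,SEEDPER_1,0.79,0.79,1
Abutilon theophrasti,SEEDWEIGHT,9.0,10.6,4
Alopecurus myosuroides,COMPHEIGHT,115,115,1
Alopecurus myosuroides,COMPHYP_1,0.02,1.43,17
Alopecurus myosuroides,FECUNDITY_2,4.93,4.93,1
Alopecurus myosuroides,GERMBASE,0.0,0.0,1
Alopecurus myosuroides,EMDEPTH_2,8,12,2
Alopecurus myosuroides,EMTOT_1,40.4,40.4,1
Alopecurus myosuroides,SEEDPER_1,0.34,1.85,6
Alopecurus myosuroides,SEEDWEIGHT,1.55,2.19,6
Ambrosia artemisiifolia,COMPHEIGHT,120,180,3
Ambrosia artemisiifolia,COMPHYP_1,7.07,25.9,7
Ambrosia artemisiifolia,GERMBASE,5.0,6.0,2
Ambrosia artemisiifolia,EMDEPTH_2,4,6.5,3
Ambrosia artemisiifolia,SEEDWEIGHT,1.72,3.99,10
Apera spica-venti,COMPHEIGHT,100,100,1
Apera spica-venti,COMPHYP_1,0.08,3.4,7
Apera spica-venti,FECUNDITY_2,6.55,6.55,1
Apera spica-venti,EMDEPTH_2,1,3.5,2
Apera spica-venti,EMTOT_1,30,30,1
Apera spica-venti,SEEDPER_1,0.43,0.43,1
Apera spica-venti,SEEDWEIGHT,0.1,0.1,2
Anisantha sterilis,COMPHEIGHT,70,100,5
Anisantha sterilis,FECUNDITY_2,4.51,4.51,1
Anisantha sterilis,GERMBASE,3.0,3.0,1
Anisantha sterilis,EMDEPTH_2,4.5,13,4
Anisantha sterilis,EMTOT_1,65,65,1
Anisantha sterilis,SEEDPER_1,1.0,1.0,1
Anisantha sterilis,SEEDWEIGHT,5.26,8.37,7
Centaurea cyanus,COMPHEIGHT,60,80,7
Centaurea cyanus,COMPHYP_1,0.11,0.25,3
Centaurea cyanus,GERMBASE,1.7,5.0,4
Centaurea cyanus,EMDEPTH_2,3,10,7
Centaurea cyanus,EMTOT_1,11,20,3
Centaurea cyanus,SEEDPER_1,5.0,5.0,1
Centaurea cyanus,SEEDWEIGHT,3.28,4.80,7
Chenopodium album,COMPHEIGHT,60,60,1
Chenopodium album,FECUNDITY_2,6.04,7.36,4
Chenopodium album,GERMBASE,5.8,5.8,1
Chenopodium album,EMDEPTH_2,6,6,1
Chenopodium album,EMTOT_1,7.8,15.8,2
Chenopodium album,SEEDWEIGHT,0.49,0.79,6
Echinochloa crus-galli,COMPHEIGHT,75,110,2
Echinochloa crus-galli,FECUNDITY_2,6.15,6.15,1
Echinochloa crus-galli,GERMBASE,6.2,13,5
Echinochloa crus-galli,EMDEPTH_2,7.5,7.5,1
Echinochloa crus-galli,EMTOT_1,0,100,4
Echinochloa crus-galli,SEEDPER_1,0.69,0.69,1
Echinochloa crus-galli,SEEDWEIGHT,0.89,2.35,6
Fallopia convolvulus,COMPHEIGHT,64,64,1
Fallopia convolvulus,FECUNDITY_2,4.55,4.55,1
Fallopia convolvulus,EMDEPTH_2,9.5,19,2
Fallopia convolvulus,SEEDWEIGHT,5.06,7.0,4
Galium aparine,COMPHEIGHT,67,180,3
Galium aparine,COMPHYP_1,0.09,23,44
Galium aparine,FECUNDITY_2,3.12,5.09,3
Galium aparine,GERMBASE,0.0,0.0,1
Galium aparine,EMDEPTH_2,10,10,1
Galium aparine,EMTOT_1,58,58,1
Galium aparine,SEEDPER_1,0.76,1.90,3
Galium aparine,SEEDWEIGHT,6.64,13.06,5
Papaver rhoeas,COMPHEIGHT,88,88,1
Papaver rhoeas,COMPHYP_1,0.1,0.1,1
Papaver rhoeas,FECUNDITY_2,6.38,7.03,2
Papaver rhoeas,GERMBASE,1.0,1.0,1
Papaver rhoeas,EMTOT_1,3,70,2
Papaver rhoeas,SEEDPER_1,5,44,2
Papaver rhoeas,SEEDWEIGHT,0.07,0.20,4
Poa annua,COMPHEIGHT,38,38,1
Poa annua,EMTOT_1,35,35,1
Poa annua,SEEDWEIGHT,0.19,0.48,11
Polygonum aviculare,COMPHEIGHT,58,58,1
Polygonum aviculare,FECUNDITY_2,4.66,4.66,1
Polygonum aviculare,GERMBASE,0.0,8.0,2
Polygonum aviculare,EMDEPTH_2,3,16,2
Polygonum aviculare,EMTOT_1,32,32,1
Polygonum aviculare,SEEDWEIGHT,0.68,3.0,7
Persicaria lapathifolia,GERMBASE,1.7,1.7,1
Persicaria lapathifolia,EMDEPTH_2,6.5,6.5,1
Persicaria lapathifolia,EMTOT_1,50.1,50.1,1
Persicaria lapathifolia,SEEDWEIGHT,1.50,2.91,6
Raphanus raphanistrum,COMPHEIGHT,200,200,1
Raphanus raphanistrum,COMPHYP_1,0.51,1.71,6
Raphanus raphanistrum,GERMBASE,5,5,1
Raphanus raphanistrum,EMTOT_1,1.4,10.4,4
Raphanus raphanistrum,SEEDPER_1,1.0,1.0,2
Raphanus raphanistrum,SEEDWEIGHT,2.10,4.76,3
Sinapis arvensis,COMPHEIGHT,93,99.5,3
Sinapis arvensis,COMPHYP_1,0.3,7.0,4
Sinapis arvensis,FECUNDITY_2,3.6,4.93,3
Sinapis arvensis,GERMBASE,10,10,1
Sinapis arvensis,EMTOT_1,20,80,4
Sinapis arvensis,SEEDPER_1,2.3,2.3,1
Sinapis arvensis,SEEDWEIGHT,0.92,2.33,7
Solanum nigrum,COMPHEIGHT,24.9,78.1,4
Solanum nigrum,FECUNDITY_2,7.34,7.34,1
Solanum nigrum,GERMBASE,7.5,11.5,4
Solanum nigrum,EMDEPTH_2,6,15,2
Solanum nigrum,SEEDPER_1,0.86,0.86,1
Solanum nigrum,SEEDWEIGHT,0.70,1.02,8
Stellaria media,COMPHEIGHT,61.5,61.5,1
Stellaria media,COMPHYP_1,0.016,4.2,32
Stellaria media,FECUNDITY_2,5.2,6.46,4
Stellaria media,GERMBASE,1.4,4.7,2
Stellaria media,EMDEPTH_2,5,10.5,4
Stellaria media,EMTOT_1,1.7,30,3
Stellaria media,SEEDPER_1,1.46,1.7,2
Stellaria media,SEEDWEIGHT,0.33,0.67,9
Tripleurospermum inodorum,COMPHEIGHT,100,109,2
Tripleurospermum inodorum,COMPHYP_1,1.31,1.31,1
Tripleurospermum inodorum,FECUNDITY_2,6.31,6.67,3
Tripleurospermum inodorum,GERMBASE,1.9,1.9,1
Tripleurospermum inodorum,EMDEPTH_2,8,8,1
Tripleurospermum inodorum,SEEDPER_1,1.6,1.6,1
Tripleurospermum inodorum,SEEDWEIGHT,0.27,0.74,15
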