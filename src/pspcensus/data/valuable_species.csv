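species,valid_name,commercial_name,code,issongo_name,category
Entandrophragma cylindricum,,Sapelli,01,Mboyo,A
Entandrophragma utile,,Sipo,02,Bokoï,A
Entandrophragma candollei,,Kosipo,03,Kanga-Bona,A
Entandrophragma angolense,,Tiama,04,Kanga,A
Afzelia africana,,Doussié,05,Mokala,A
Khaya anthotheca,,Acajou,06,Dèkè,A
Lovoa trichilioïdes,,Dibétou,07,Mboyo-Kondi,A
Chlorophora excelsa,Milicia excelsa,Iroko,08,Mokoko,A
Pterocarpus soyauxii,,Padouk,09,Tola,A
Nauclea diderrichii,,Bilinga,10,Kido,A
Autranella congolensis,,Mukulungu,11,Bouanga,A
Morus mesozygia,,Difou,12,Bonde,A
Lophira alata,,Azobé,13,Ngolo,A
Erythrophleum guineense,Erythrophleum suaveolens,Tali,14,Kassa,A
Guarea cedrata,Leplaea cedrata,Bossé,15,Bombolo-Bombolo,A
Triplochiton scleroxylon,,Ayous,16,Cepa,B
Terminalia superba,,Limba,17,Nganga,B
Piptadeniastrum africanum,,Dabéma,18,Mokoungou,B
Picnanthus angolensis,,Ilomba,19,Kolo,B
Ceiba pentandra,,Fromager,20,Bouma,B
Ricinodendron heudelotii,,Essessang,21,MBoboko,B
Staudtia stipitata,Staudtia kamerunensis,Niové,22,Molanga,B
Canarium schweinfurthii,,Aiélé,23,Fatou,B
Alstonia congensis,,Emien,24,Mogouga,B
Sterculia oblonga,Eribroma oblongum,Eyong,25,GBoyo,B
Diospyros crassiflora,,Ebène,26,Bingo,B
Oxystigma oxyphyllum,Prioria oxyphylla,Tchitola,27,Ngoulou,B
Nesogordonia papaverifera,,Kotibé,28,Molo-Fongoli,B
Fagara lemairei,Zanthoxyllum lemairei,Olon,29,Bolongo,B
Aningeria sp.,Pouteria sp.,Aniégré,30,MBoulou,B
Mammea africana,,Oboto,31,Bolélé,B
Ongokea gore,,Angueuk,32,Gbana,B
Petersianthus macrocarpus,,Essia,33,Mossoba,B
Antiaris africana,,Ako,34,Mongodou,B
Funtumia elastica,,Pri,35,Mondembo,B
Cola nitida,,Colatier,36,Mako,B
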