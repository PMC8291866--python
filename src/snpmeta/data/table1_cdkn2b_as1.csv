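study_id,author,year,origin,variant,phenotype,ethnicity,control_source,case_hom_effect,case_het,case_hom_other,ctrl_hom_effect,ctrl_het,ctrl_hom_other,method
Suleiman2019_Iraq_rs1333049,Suleiman,2019,Iraq,rs1333049,CAD,West Asian,HB,9,22,19,4,23,23,Primex PCR
Shakhtshneider2019_Russia_rs1333049,Shakhtshneider,2019,Russia,rs1333049,MI,Caucasian,PB,39,51,28,554,1330,726,RT-PCR
Kalpana2019_India_rs1333049,Kalpana,2019,India,rs1333049,CAD,West Asian,PB,30,38,23,102,222,112,MassARRAY
Huang2019_China_rs1333049,Huang,2019,Mainland China,rs1333049,CAD,East Asian,HB,110,263,128,94,254,148,MassARRAY
Kashyap2018_India_rs1333049,Kashyap,2018,India,rs1333049,CAD,West Asian,HB,117,316,79,46,176,50,PCR-RFLP
Yang2018_China_rs1333049,Yang,2018,Mainland China,rs1333049,CAD,East Asian,HB,111,269,162,100,273,176,MassARRAY
Pignataro2017_Italy_rs1333049,Pignataro,2017,Italy,rs1333049,CAD,Caucasian,NA,251,342,118,215,391,149,NA
Li2017_China_rs1333049,Li,2017,Mainland China,rs1333049,CAD,East Asian,NA,198,239,118,129,223,128,TaqMan
Haslacher2016_Austria_rs1333049,Haslacher,2016,Austria,rs1333049,MI,Caucasian,PB,118,236,139,97,222,112,TaqMan
Foroughmand2015_Iran_rs1333049,Foroughmand,2015,Iran,rs1333049,CAD,West Asian,HB,31,111,28,25,67,8,ARMS-PCR
Cakmak2015_Turkey_rs1333049,Cakmak,2015,Turkey,rs1333049,CAD,Caucasian,HB,54,120,46,85,115,40,RT-PCR
Pinos2014_Spain_rs1333049,Pinos,2014,Spain,rs1333049,CAD,Caucasian,HB,45,53,54,105,153,85,TaqMan
Pinos2014_Japan_rs1333049,Pinos,2014,Japan,rs1333049,CAD,East Asian,HB,158,373,211,193,485,242,TaqMan
Jansen2014_Norway_rs1333049,Jansen,2014,Norway,rs1333049,CAD,Caucasian,PB,238,368,212,647,1009,438,MassARRAY
Gong2014_China_rs1333049,Gong,2014,Mainland China,rs1333049,CAD,East Asian,HB,133,248,164,160,358,207,MassARRAY
Bhanushali2013_India_CAD_rs1333049,Bhanushali,2013,India,rs1333049,CAD,West Asian,HB,33,57,7,34,80,37,TaqMan
Bhanushali2013_India_MI_rs1333049,Bhanushali,2013,India,rs1333049,MI,West Asian,HB,38,60,22,34,80,37,TaqMan
Zeng2013_China_rs1333049,Zeng,2013,Mainland China,rs1333049,CAD,East Asian,PB,110,168,81,75,197,126,PCR-RFLP
Ahmed2013_Pakistan_rs1333049,Ahmed,2013,Pakistan,rs1333049,MI,West Asian,HB,63,166,65,23,180,87,TaqMan
Qi2012_China_rs1333049,Qi,2012,Mainland China,rs1333049,MI,East Asian,HB,21,79,42,43,99,50,PCR-RFLP
Lin2011_Taiwan_rs1333049,Lin,2011,Taiwan,rs1333049,MI,East Asian,HB,105,218,100,311,655,395,TaqMan
Guo2011_China_rs1333049,Guo,2011,Mainland China,rs1333049,CAD,East Asian,PB,156,327,187,358,661,321,RT-PCR
Xie2011_China_rs1333049,Xie,2011,Mainland China,rs1333049,CAD,East Asian,PB,659,1140,506,241,525,295,TaqMan
Scheffold2011_Germany_rs1333049,Scheffold,2011,Germany,rs1333049,MI,Caucasian,PB,246,518,212,205,502,292,RT-PCR
Mendonca2011_Portugal_rs1333049,Mendonca,2011,Portugal,rs1333049,CAD,Caucasian,PB,258,348,117,200,321,162,TaqMan
Ghazouani2010_Tunisia_rs1333049,Ghazouani,2010,Tunisia,rs1333049,CAD,African,PB,72,137,83,88,151,84,TaqMan
Saleheen2010_Pakistan_rs1333049,Saleheen,2010,Pakistan,rs1333049,MI,West Asian,PB,697,1273,617,609,1290,674,IBC array
Peng2009_China_rs1333049,Peng,2009,Mainland China,rs1333049,MI,East Asian,PB,156,265,99,116,285,159,TaqMan
Hiura2008_Japan_rs1333049,Hiura,2008,Japan,rs1333049,MI,East Asian,PB,170,279,137,592,1204,636,TaqMan
Hinohara2008_Korea_rs1333049,Hinohara,2008,Korea,rs1333049,CAD,East Asian,PB,186,335,158,161,353,192,TaqMan
Hinohara2008_Japan_rs1333049,Hinohara,2008,Japan,rs1333049,CAD,East Asian,PB,178,312,114,259,606,286,TaqMan
Samani2007_German_rs1333049,Samani,2007,German,rs1333049,MI,Caucasian,PB,158,453,233,425,831,349,GeneChip
Samani2007_UK_rs1333049,Samani,2007,UK,rs1333049,CAD,Caucasian,PB,586,960,378,676,1431,829,GeneChip
Hua2020_China_rs4977574,Hua,2020,Mainland China,rs4977574,CAD,East Asian,HB,152,297,149,48,122,87,MassARRAY
Temel2019_Turkey_rs4977574,Temel,2019,Turkey,rs4977574,CAD,Caucasian,HB,14,33,24,38,76,39,PCR-RFLP
Kalpana2019_India_rs4977574,Kalpana,2019,India,rs4977574,CAD,West Asian,PB,31,36,23,100,230,106,MassARRAY
Tang2017_China_rs4977574,Tang,2017,Mainland China,rs4977574,CAD,East Asian,HB,116,136,37,166,134,38,RT-PCR
Cao2016_China_rs4977574,Cao,2016,Mainland China,rs4977574,CAD,East Asian,HB,176,272,117,134,255,152,PCR-RFLP
Matsuoka2015_Japan_rs4977574,Matsuoka,2015,Japan,rs4977574,MI,East Asian,PB,476,898,448,501,1132,651,Suspension array
Beigi2015_Iran_rs4977574,Beigi,2015,Iran,rs4977574,CAD,West Asian,HB,34,44,22,32,44,17,TaqMan
Huang2014_China_rs4977574,Huang,2014,Mainland China,rs4977574,CAD,East Asian,HB,163,305,122,77,267,138,MassARRAY
Sakalar2013_Turkey_rs4977574,Sakalar,2013,Turkey,rs4977574,MI,Caucasian,HB,14,22,8,4,11,13,PCR-RFLP
Saade2011_Lebanon_rs4977574,Saade,2011,Lebanon,rs4977574,CAD,West Asian,PB,627,685,208,156,195,72,Illumina
Saleheen2010_Pakistan_rs4977574,Saleheen,2010,Pakistan,rs4977574,MI,West Asian,PB,746,1242,596,636,1298,642,IBC array
Helgadottir2007_Iceland_rs4977574,Helgadottir,2007,Iceland,rs4977574,MI,Caucasian,PB,556,1105,554,964,2335,1507,GWAS
Helgadottir2007_Philadelphia_rs4977574,Helgadottir,2007,Philadelphia,rs4977574,MI,Caucasian,PB,180,286,103,119,246,130,GWAS
Helgadottir2007_Atlanta_rs4977574,Helgadottir,2007,Atlanta,rs4977574,MI,Caucasian,PB,188,274,115,325,597,332,GWAS
Helgadottir2007_Durham_rs4977574,Helgadottir,2007,Durham,rs4977574,MI,Caucasian,PB,316,549,267,144,383,187,GWAS
Samani2007_German_rs4977574,Samani,2007,German,rs4977574,MI,Caucasian,PB,169,452,239,463,826,354,GeneChip
Samani2007_UK_rs4977574,Samani,2007,UK,rs4977574,CAD,Caucasian,PB,605,937,382,698,1435,804,GeneChip
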