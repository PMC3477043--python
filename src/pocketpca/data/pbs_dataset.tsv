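organism	family	table	accession	pbs_string	group	flags
Human (isotype I)	isotype	animal	NM_178014.2	EVDDHASFTSRRGL	C
Human (isotype IIa)	isotype	animal	NM_001069.2	EVDDHASFTSRRGL	C
Human (isotype IIb)	isotype	animal	NM_178012.4	EVDDHASFTSRRGL	C
Human (isotype IVb)	isotype	animal	NM_006088.5	EVDDHASFTSRRGL	C
Human (isotype III)	isotype	animal	NM_006086.3	EVDDHASFTARRGL	D
Human (isotype IVa)	isotype	animal	NM_006087.2	EVDDHASFTSRRGL	C
Human (isotype V)	isotype	animal	NM_032525.1	EVDDHASFTSRRGL	C
Human (isotype VI)	isotype	animal	NM_030773.3	EMEDHLSFTAQRGL	B
Ancylostoma duodenale	animal	animal	66734014	EVDDHVSFSAKRGL	D
Haemonchus contortus	animal	animal	159161	EVDDHVSFSAKRGL	D
Strongyloides stercoralis	animal	animal	62836546	EVEDHMSFAARKGL	D
Onchocerca volvulus	animal	animal	3046907	EVDDHVSFSARRGL	D
Dirofilaria immitis	animal	animal	3046903	EVDDHVSFSARRGL	D
Brugia pahangi	animal	animal	156096	EVDDHVSFSARRGL	D
Bombyx mori	animal	animal	19773428	EIDDHLSFTSRRGL	C
Saimiri sciureus	animal	animal	16974673	EVDDHASFSSRRGL	C
Enteroctopus dofleini	animal	animal	159727	EVEDHASFTSRTGL	C
Glossina morsitans	animal	animal	289741319	EVDDHASFTSRKGL	C
Sus scrofa	animal	animal	135490	EVDDHASFTSRRGL	C
Bos Taurus	animal	animal	50844501	EVDDHASFTSRRGL	C
Notothenia coriiceps	animal	animal	10242164	EVDDHASFTSRRGL	C
Drosophila melanogaster	animal	animal	24645350	EVDDHASFTSRRGL	C
Patella vulgata	animal	animal	1335661	EVDDHASFTSRRGL	C
Crassostrea gigas	animal	animal	56603670	EVDDHASFTSRRGL	C
Loligo pealei	animal	animal	51860821	EVDDHASFTSRRGL	C
Macaca mulatta	animal	animal	74136187	EVDDHASFTSRRGL	C
Pan troglodytes	animal	animal	90960962	EVDDHASFTSRRGL	C
Cricetulus griseus	animal	animal	49481	EVDDNASFTSRRGL	C
Caenorhabditis elegans	animal	animal	6892	EVDDHASFTSRRGL	C
Chionodraco rastrospinosus	animal	animal	10242186	EVDDHASFTSRRGL	C
Trichuris trichiura	animal	animal	4558495	EVDDHASFTSRRGL	C
Papio hamadryas	animal	animal	16974663	EVDDHASFTSRRGL	C
Heliothis virescens	animal	animal	1769528	EVDDHASFTSRRGL	C
Aplysia californica	animal	animal	30088884	EVDDHASFTSRRGL	C
Fasciola hepatica	animal	animal	17402390	EVDDHASFTSRRGL	C
Paracentrotus lividus	animal	animal	135489	EVDDHASFTSRRGL	C
Meriones unguiculatus	animal	animal	7838279	EVDDHASFTSRRGL	C
Echinococcus multilocularis	animal	animal	7838199	EVDDHASFTSRRGL	C
Lentinus sajor-caju	fungi	fungi	4455142	EVDDHISFTARRGC	D	duplicate
Schizophyllum commune	fungi	fungi	173523	EVDDHFSFTARRGL	D
Ustilago maydis	fungi	fungi	74699315	EVDDHLSFTARRGL	D
Melampsora lini	fungi	fungi	11229034	EVDDHISFTARRGL	D
Cochliobolus heterostrophus	fungi	fungi	55982602	EVDDHSSFTSRRGL	C
Schizosaccharomyces pombe	fungi	fungi	173523	STDDHAAFAAIKDL	B
Saccharomyces cerevisiae	fungi	fungi	3435	ETGDNSSYTAIQGL	B
Candida albicans	fungi	fungi	170938	ETGENSSYTSMKDL	B
Verticillium tricorpus	fungi	fungi	77023508	QNGDHASFTSRRGL	A
Phaeosphaeria nodorum	fungi	fungi	299296	QTGDHASFTSRRGL	A
Phaeosphaeria avenaria	fungi	fungi	58119500	QTGDHASFTSRRGL	A
Venturia inaequalis	fungi	fungi	170600	QTGDHASFTSRRGL	A
Cercospora beticola	fungi	fungi	61678005	QTGDHASFTSRRGL	A
Monilinia fructicola	fungi	fungi	30961893	QTGDHASFTSRRGL	A
Aspergillus flavus	fungi	fungi	166496	QTGDHASFTSRRGL	A
Emericella nidulans	fungi	fungi	168105	QTGDHASFTSRRGL	A
Ajellomyces capsulatus	fungi	fungi	639766	QTGDHASFTSRRGL	A
Mycosphaerella pini	fungi	fungi	2852439	QTGDHASFTSRRGL	A
Botryotinia fuckeliana	fungi	fungi	1002511	QTGDHASFTSRRGL	A
Erysiphe pisi	fungi	fungi	602578	QTGDHASFTSRRGL	A
Penicillium digitatum	fungi	fungi	1060942	QTGDHASFTSRRGL	A
Pestalotiopsis microspora	fungi	fungi	6652864	QTGDHASFTSRRGL	A
Rhynchosporium secalis	fungi	fungi	1263904	QTGDHASFTSRRGL	A
Epichloe typhina	fungi	fungi	2718	QTGDYASFTSRRGL	A
Gibberella fujikuroi	fungi	fungi	849160	QTGDYASFTSRRGL	A
Neotyphodium coenophialum	fungi	fungi	2293	QTGDYASFTSRRDL	A
Gibberella zeae	fungi	fungi	32130590	QTGDYASFTSRRGL	A
Glomerella graminicola	fungi	fungi	167300	QTGHHRSFTS-KGL	A
Pneumocystis carinii	fungi	fungi	169400	STGDHASFTSKRGL	A
Lentinus sajor-caju	plant	plant	4455142	EVDDHISFTARRGC	C	duplicate
Daucus carota	plant	plant	1488052	EVDDHGSFTSRRGL	C
Oryza sativa	plant	plant	460991	EVDDHASFTSRRGL	C
Eleusine indica	plant	plant	4415996	EVDDHASFTSRRGL	C
Populus trichocarpa	plant	plant	224106013	EVDDHASFTSRRGL	C
Cicer arietinum	plant	plant	1403143	EVDDHASFTSRKNL	C
Lotus japonicus	plant	plant	244539475	EVDDHASFTSRKGL	C
Eucalyptus grandis	plant	plant	153799899	EVDDHASFTSRKGL	C
Ricinus communis	plant	plant	255564502	EVDDHASFTSRKGL	C
Glycine max	plant	plant	312989	EVDDHASFTSRKGL	C
Citrus maxima	plant	plant	223018283	EVDDHASFTSRKGL	C
Zea mays	plant	plant	295851	EVADHASFTSRHGL	C
Solanu tuberosum	plant	plant	609270	EVDDHASFTSRTGL	C
Solanum lycopersicum	plant	plant	77963735	EVDDHASFTSRTGL	C
Nicotiana attenuata	plant	plant	40036995	EVDDHASFTSRTGL	C
Hordeum vulgare	plant	plant	1743277	EVDDHASFTSRTGL	C
Medicago sativa	plant	plant	14331109	EVDDHTSFTSRTGL	C
Capsicum annuum	plant	plant	145388977	EVDDHASFTSRTGL	C
Physcomitrella patens	plant	plant	37038246	EVEDHASFTSRTGL	C
Lupinus albus	plant	plant	402636	EVADHASFTSRTGL	C
Pisum sativum	plant	plant	20758	EVADHASFTSRTGL	C
Arabidopsis thaliana	plant	plant	20148289	EVADHASFTSRTGL	C
Setaria viridis	plant	plant	51988178	EVADHASFTSRTGL	C
Prunus salicina	plant	plant	205326619	EVADHASFTSRTGL	C
Zinnia elegans	plant	plant	5668669	EVTDHASFTSRTGL	C
Anemia phyllitidis	plant	plant	296498	EVTDHASFTSRVGL	C
Triticum aestivum	plant	plant	4098333	EVGDHASFTSRVGL	C
Gossypium hirsutum	plant	plant	19569609	EVADHASFTSRIGL	C
Babesia bovis	protist	protist	155874	EVDDHASFTSRKGL	C
Babesia microti	protist	protist	29420520	EVDDHASFTSRKGL	C
Plasmodium falciparum	protist	protist	295762	EVDDHASFTSRKGL	C
Tetrahymena pyriformis	protist	protist	4079637	EVDDHASFTSRKGL	C
Tetrahymena thermophila	protist	protist	161737	EVDDHASFTSRKGL	C
Stylonychia mytilus	protist	protist	6007456	EVDDHASFTSRKGL	C
Euplotes octocarinatus	protist	protist	9309	EVDDHASFTSRKGL	C
Chlamydomonas incerta	protist	protist	2155306	EVDDHASFTSRKGL	C
Chlamydomonas reinhardtii	protist	protist	167456	EVDDHASFTSRKGL	C
Achlya klebsiana	protist	protist	166302	EVDDHASFTSRKGL	C
Leishmania major	protist	protist	68128910	EVDDHASFTSRKGL	C
Pythium ultimum	protist	protist	6652866	EVDDHASFTSRKGL	C
Eimeria tenella	protist	protist	639490	EVDDHASFTSRKGL	C
Toxoplasma gondii	protist	protist	161939	EVDDHASFTSRKGL	C
Plasmodium yoelii yoelii	protist	protist	23481527	EVDDHASFTSRKGL	C
Moneuplotes crassus	protist	protist	290685	EVDDHASFTSRKGL	C
Paramecium tetraurelia	protist	protist	38520885	EVDDHASFTSRKGL	C
Palpitomonas bilix	protist	protist	295443942	EVDDHASFTSRKGL	C
Leucocryptos marina	protist	protist	238617571	EVDDHASFTSRKGL	C
Volvox carteri	protist	protist	302849658	EVDDHASFTSRKGL	C
Trypanosoma brucei rhodesiens	protist	protist	135500	EVDDHASFTSRKGL	C
Bodo saltans	protist	protist	206598211	EVDDHASFTSRKGL	C
Leishmania mexicana	protist	protist	159416	EVDDHASFTSRKGL	C
Polytomella agilis	protist	protist	135494	EVDDHASFTSRKGL	C
Naegleria gruberi	protist	protist	829213	EVDDHISFTSRRGL	C
Thalassiosira weissflogii	protist	protist	8926601	EVDDHACYTSRKGL	C
Phytophthora cinnamomi	protist	protist	2951981	EVDDHASFTSRQGL	C
Porphyra yezoensis	protist	protist	29150706	EVEDKGSYSADTGE	D
Cyanidioschyzon merolae	protist	protist	29539330	EVEDKGSLTATKGL	D
Porphyra purpurea	protist	protist	1067176	EVEDKGSYSADTGE	D
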