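cdna	protein	impact	associated_germline	context	refs
cnLOH		Deletion	p.(Gln86*);p.(Arg267*);p.(Asn361Tyr);p.(Arg364*);p.(Leu365Pro);p.(Trp386*);p.(Gln408Arg);p.(Trp476*);p.(Leu548Pro);p.(Ile664Ser);p.(Arg764*);p.(Arg879Trp);p.(Arg898Trp);none	pbmah	12,14,24,26,28,34,37,44,46
cnLOH		Deletion	p.(Arg267*)	meningioma	26
Exons 4-6 deletion		Deletion	none	pbmah	34
c.91A>T	p.(Lys31*)	Nonsense	p.(Ala296Cysfs*34)	pbmah	12,13
c.118del	p.(Leu40*)	Nonsense	large deletion	pbmah	12,13
c.170dupG	p.(Ile58Asnfs*45)	Frameshift	p.(Ala110Argfs*9)	pbmah	22
c.172del	p.(Ile58Serfs*79)	Frameshift	p.(Arg764*)	pbmah	46
c.205_322del	p.(Pro69Alafs*29)	Frameshift	p.(Gln228*)	pbmah	87
c.210_297del	p.(Ala72Leufs*36)	Frameshift	p.(Ala702_Ser706del)	pbmah	12,13
c.226C>T	p.(Arg76*)	Nonsense	p.(Ala104Glyfs*7)	pbmah	12,13
c.231_265del	p.(Ala78Argfs*13)	Frameshift	p.(Cys813Valfs*104)	pbmah	34
c.239C>G	p.(Ala80Gly)	Missense	p.(Ala702_Ser706del)	pbmah	12,13
c.243_289del	p.(Ser82Valfs*5)	Frameshift	p.(Ala702_Ser706del)	pbmah	12,13
c.247_256del	p.(Ala83Argfs*51)	Frameshift	p.(His808Pro)	pbmah	24
c.247G>C	p.(Ala83Pro)	Missense	p.(Trp476*)	pbmah	45
c.249_270del	p.(Ser85Profs*45)	Frameshift	p.(Arg315Trp)	pbmah	89
c.261_264del	p.(Gly88Profs*48)	Frameshift	p.(Arg267*)	pbmah	46
c.267del	p.(Gly90Alafs*47)	Frameshift	p.(Gln228*)	pbmah	87
c.276_288del	p.(Pro93Argfs*40)	Frameshift	p.(Arg619*)	pbmah	12,13
c.279del	p.(Ser94Argfs*43)	Frameshift	p.(Arg654*)	pbmah	89
c.283_286del	p.(Ser95Profs*41)	Frameshift	p.(Arg811Pro)	pbmah	82
c.283_289del	p.(Ser95Argfs*40)	Frameshift	p.(Gln228*)	pbmah	87
c.284C>A	p.(Ser95*)	Nonsense	p.(Arg619*)	pbmah	92
c.290_294del	p.(Ala97Glyfs*4)	Frameshift	p.(Ser779*)	pbmah	24
c.294del	p.(Gly99Glufs*38)	Frameshift	p.(Arg619*)	pbmah	92
c.295G>T	p.(Gly99*)	Nonsense	p.(Asn361Tyr)	pbmah	46
c.306_318del	p.(Pro103Argfs*30)	Frameshift	p.(Leu548Pro)	pbmah	46
c.306_342del	p.(Pro103Argfs*22)	Frameshift	p.(Ala110Argfs*9)	pbmah	22
c.310del	p.(Ala104Profs*33)	Frameshift	p.(Gln228*)	pbmah	87
c.311del	p.(Ala106Argfs*31)	Frameshift	p.(Ala110Argfs*9)	pbmah	22
c.316dup	p.(Ala106Glyfs*13)	Frameshift	p.(Ala110Argfs*9)	pbmah	22
c.319_320del	p.(Ser107Glyfs*11)	Frameshift	p.(Arg898Trp)	pbmah	12,13
c.325_326delinsT	p.(Pro109Serfs*28)	Frameshift	p.(Gly65Alafs72*)	pbmah	37
c.327del	p.(Ala110Profs*27)	Frameshift	p.(Glu430*);p.(Trp476*)	pbmah	12,13,45
c.346del	p.(Ser116Argfs*21)	Frameshift	p.(Trp476*)	pbmah	45
c.347_357del	p.(Ser116Tyrfs*67)	Frameshift	p.(Gln228*)	pbmah	87
c.415T>C	p.(Cys139Arg)	Missense	p.(Arg267*)	pbmah	12,13
c.420T>A	p.(Cys140*)	Nonsense	p.(Arg267*)	pbmah	46
c.430del	p.(Ala144Argfs*16)	Frameshift	p.(Arg764*)	pbmah	46
c.435C>A	p.(Cys145*)	Nonsense	p.(Arg619*)	pbmah	92
c.456_475 + 5del		Splice	p.(Arg267*)	pbmah	12,13
c.476-1G>A		Splice	p.(Trp476*)	pbmah	45
c.608del	p.(Ser203Thrfs*2)	Frameshift	p.(Trp476*)	pbmah	45
c.617_845del	p.(Ala206Aspfs*22)	Frameshift	p.(Arg267*)	pbmah	12,13
c.658del	p.(Leu220Serfs*35)	Frameshift	p.(Leu754Pro)	pbmah	13
c.671C>A	p.(Ala224Glu)	Missense	p.(Arg315Trp)	pbmah	89
c.682C>T	p.(Gln228*)	Nonsense	none	pbmah	34
c.696del	p.(Leu233Trpfs*22)	Frameshift	p.(Arg267*)	pbmah	46
c.703C>T	p.(Gln235*)	Nonsense	p.(Cys657Arg);p.(Arg173*)	pbmah	13,86
c.789_808del	p.(Glu264Profs*5)	Frameshift	p.(Trp476*)	pbmah	45
c.807C>A	p.(Cys269*)	Nonsense	p.(Trp476*)	pbmah	45
c.913del	p.(Leu305Serfs*9)	Frameshift	p.(Asn361Tyr)	pbmah	46
c.943C>T	p.(Arg315Trp)	Missense	p.(Leu548Pro)	pbmah	12,13
c.992T>C	p.(Leu331Pro)	Missense	p.(Gly57Glufs*80)	pbmah	12,13
c.1033C>T	p.(Gln345*)	Nonsense	p.(Trp476*)	pbmah	45
c.1039_1049del	p.(Pro347Glyfs*8)	Frameshift	p.(Arg267*)	pbmah	46
c.1042del	p.(Leu348Trpfs*27)	Frameshift	p.(Arg764*)	pbmah	37
c.1059_1080del	p.(Cys353*)	Nonsense	p.(Trp476*)	pbmah	45
c.1059C>A	p.(Cys353*)	Nonsense	p.(Trp476*)	pbmah	45
c.1084C>T	p.(Arg362Trp)	Missense	p.(Ala110Argfs*9)	pbmah	22
c.1085G>T	p.(Arg362Leu)	Missense	p.(Phe700del)	pbmah	12,13
c.1158G>A	p.(Trp386*)	Nonsense	p.(Arg267*)	pbmah	46
c.1174del	p.(Ala392Leufs*69)	Frameshift	p.(Arg764*)	pbmah	46
c.1222C>T	p.(Gln408*)	Nonsense	p.(Arg267*)	pbmah	46
c.1297G>T	p.(Glu433*)	Nonsense	p.(Ala110Argfs*9)	pbmah	22
c.1330del	p.(Thr444Profs*17)	Frameshift	p.(Arg593Trp)	pbmah	21
c.1369A>T	p.(Arg457Trp)	Missense	p.(Gln228*)	pbmah	88
c.1474del	p.(Ala492Profs*52)	Frameshift	p.(Cys657Arg)	pbmah	13
c.1507_1508del	p.(Thr503Profs*34)	Frameshift	p.(Ala110Argfs*9)	meningioma	22
c.1549G>A	p.(Glu517Lys)	Missense	p.(Arg654*)	pbmah	89
c.1572_1607del	p.(Ala525_Pro536del)	In frame	p.(Arg619*)	pbmah	92
c.1671_1678dup	p.(Gly560Alafs*73)	Frameshift	p.(Arg267*)	pbmah	46
c.1712C>G	p.(Ser571*)	Nonsense	p.(Arg173*)	pbmah	86
c.1746del	p.(Phe583Serfs*47)	Frameshift	p.(Gln86*)	pbmah	12,13
c.1751T>A	p.(Val584Glu)	Missense	p.(Trp476*)	pbmah	45
c.1777C>T	p.(Arg593Trp)	Missense	p.(Arg267*)	pbmah	46
c.1843C>G	p.(His615Asp)	Missense	p.(Phe14Tyr)	pbmah	28
c.1851del	p.(His518Thrfs*12)	Frameshift	p.(Arg764*)	pbmah	38
c.1855C>T	p.(Arg619*)	Nonsense	p.(Arg267*)	pbmah	12,13,46
c.1864G>A	p.(Gly622Arg)	Missense	p.(Arg764*)	pbmah	46
c.1913G>A	p.(Gly638Glu)	Missense	p.(Arg267*)	pbmah	46
c.1960C>T	p.(Arg654*)	Nonsense	p.(Ala110Argfs*9)	pbmah	22
c.1971C>G	p.(Cys657Trp)	Missense	p.(Leu365Pro)	pbmah	24
c.1982T>A	p.(Leu661Gln)	Missense	p.(Arg267*)	pbmah	46
c.2011del	p.(Trp671Glyfs*18)	Frameshift	p.(Arg267*)	pbmah	46
c.2025del	p.(Leu676Trpfs*13)	Frameshift	p.(Gly323Asp)	pbmah	82
c.2029G>T	p.(Glu677*)	Nonsense	p.(Asn361Tyr)	pbmah	46
c.2053_2055del	p.(Leu685del)	In frame	c.476-1G>C	pbmah	14
c.2113del	p.(Leu705Phefs*12)	Frameshift	p.(Gly57Glufs*80)	pbmah	13
c.2116dup	p.(Ser706Phefs*32)	Frameshift	p.(Asn361Tyr)	pbmah	46
c.2123del	p.(Leu708Profs*9)	Frameshift	p.(Ala296Cysfs*34)	pbmah	13
c.2207A>C	p.(Tyr736Ser)	Missense	p.(Arg898Trp)	pbmah	12,13
c.2228C>T	p.(Ala743Val)	Missense	p.(Trp476*)	pbmah	45
c.2302G>C	p.(Ala768Pro)	Missense	p.(Pro507Leu)	pbmah	28
c.2405C>G	p.(Pro802Arg)	Missense	p.(Trp476*)	pbmah	45
c.2444del	p.(Ala815Leufs*102)	Frameshift	p.(Trp476*)	pbmah	45
c.2486G>A	p.(Gly829Asp)	Missense	none	pbmah	34
c.2522G>A	p.(Arg841His)	Missense	p.(Arg315Trp)	pbmah	89
c.2525T>A	p.(Phe842Tyr)	Missense	p.(Arg654*)	pbmah	89
c.2542G>T	p.(Glu848*)	Nonsense	p.(Arg619*)	pbmah	92
c.2599G>T	p.(Glu867*)	Nonsense	p.(Arg619*)	pbmah	38
c.2611G>T	p.(Glu871*)	Nonsense	p.(Asn361Tyr)	pbmah	46
c.2647C>T	p.(His883Tyr)	Missense	p.(Phe14Tyr)	pbmah	28
c.2666T>A	p.(Leu889Gln)	Missense	p.(Gln408Arg)	pbmah	28
c.2734G>A	p.(Glu912Lys)	Missense	p.(Arg267*)	pbmah	46
c.2755del	p.(Ala919Leufs*6)	Frameshift	p.(Arg267*)	pbmah	46
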