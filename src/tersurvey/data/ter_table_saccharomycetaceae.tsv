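# Survey of conserved telomerase-RNA (TER) substructures in Saccharomycetaceae.
# One row per species with a credible TER locus. Intervals are 1-based
# inclusive forward-strand genomic coordinates regardless of the transcribed
# strand; every feature interval is nested inside the ter interval. The TER
# 3' end is defined as 10 nt downstream of the SM binding site; the 5' end is
# approximate. coord_citation is true iff the TER coordinates were reported
# explicitly in prior literature (false marks loci first annotated by this
# kind of survey). Empty cells mean the feature was absent or could not be
# located with reasonable certainty (e.g. the Ku hairpin is absent in
# K. lactis; "absent" is encoded as an empty cell).
# Transcription notes: two obvious comma misplacements in the printed source
# were normalized rather than copied verbatim:
#   K. marxianus twj printed as "507,518-50,7671" -> 507518-507671
#   S. eubayanus ter printed as "476,134-47,7336" -> 476134-477336
species	accession	strand	ter	ku	template	est1	twj	sm1	coord_citation
K. aestuarii	AEAS01000245.1	neg	16338-17322		16940-16966	16794-16862	16378-16485	16350-16359	true
K. wickerhamii	AEAV01000432.1	pos	250-1327		662-693	765-858	1183-1290	1307-1316	true
K. marxianus	NC_036029.1	pos	506443-507711		506855-506888	506967-507049	507518-507671	507691-507700	true
K. dobzhanskii	CCBQ010000012.1	pos	461805-463090		462224-462257	462337-462499	462905-463051	463070-463079	true
K. lactis	NC_006038.1	pos	611456-612727		611890-611919	612006-612090	612532-612687	612708-612716	true
E. coryli	AZAH01000001.1	neg	269038-270368		269938-269968				false
E. cymbalariae	NC_016454.1	pos	54147-54960		54451-54480				false
E. gossypii	NC_005782.2	neg	677871-679048		678276-678305				true
Ashbya aceri	CP006020.1	neg	693543-694708		693942-693973				false
L. kluyveri	CM000690.1	pos	348600-349844	348876-348930	348957-348982	349129-349208		349825-349833	false
L. lanzarotensis	NW_019212880.1	pos	854162-855236	854389-854444		854754-854820		855217-855225	false
L. waltii	AADM01000270.1	neg	134961-136000	135698-135756	135613-135636	135409-135470		134973-134981	false
L. thermotolerans	NC_013079.1	pos	702500-703549	702730-702791	702853-702876	703022-703083		703530-703538	false
L. dasiensis	LT598456.1	pos	682034-682916	682124-682181	682261-682283			682900-682905	false
L. sp. CBS 6924	LT598470.1	neg	441802-442700	442582-442638		442229-442292		441811-441820	false
L. fermentati	LT598488.1	neg	306329-307150	307076-307129		306786-306850		306339-306348	false
L. meyersii	LT598477.1	pos	575851-576676	575886-575941		576233-576294		576657-576666	false
L. mirantina	LT598468.1	pos	690800-691797			691218-691282		691777-691786	false
L. nothofagi	LT598449.1	pos	388401-389382	388567-388624		388937-389004		389362-389371	false
T. delbrueckii	NC_016504.1	pos	709007-709780	709057-709086		709267-709336		709761-709770	false
T. microellipsoides	FYBL01000005.1	neg	426211-427050	427000-427028		426726-426817		426221-426229	false
Z. bailii	HG316456.1	neg	712655-713400			712902-712974		712665-712673	false
Z. rouxii	NC_012990.1	pos	297087-297883			297527-297616		297865-297873	false
Z. parabailii	CP019499.1	pos	455564-455975			455656-455728		455957-455965	true
T. blattae	NC_020193.1	neg	404150-405050	405003-405033		404650-404733		404165-404173	false
N. castellii	NC_016499.1	pos	381827-383194	382404-382432	382506-382519	382647-382710	382994-383155	383176-383184	true
N. dairenensis	NC_016479.1	neg	1519837-1521377	1520648-1520678	1520550-1520562	1520303-1520369	1519864-1520027	1519849-1519857	false
C. castellii	CAPW01000002.1	neg	272769-274000		273158-273179	272992-273085		272781-272789	false
N. bacillisporus	CAPX01000073.1	pos	1230-2215					2197-2204	false
C. glabrata	NC_006032.2	neg	419194-421150	421007-421081	420914-420932	420657-420852		419206-419214	true
C. bracarensis	CAPU01000044.1	pos	2586-4361		2836-2854			4342-4350	false
N. delphensis	CAPT01000167.1	neg	254761-256469		256151-256169			254773-254781	false
C. nivariensis	CAPV01000033.1	pos	87530-89215		87780-87798			89196-89204	false
S. uvarum	NOWY01000011.1	pos	45720-46940	45996-46050	46193-46203	46301-46377	46703-46848	46921-46929	false
S. eubayanus	NC_030979.1	pos	476134-477336	476392-476446	476588-476598	476694-476770	477100-477240	477317-477325	false
S. arboricola	NC_026172.1	pos	287410-288645	287705-287739	287888-287898	288019-288096	288417-288558	288626-288634	false
S. kudriavzevii	AY639012.1	pos	1-1215	284-320	424-434	585-662	981-1128	1201-1209	true
S. mikatae	AABZ01000048.1	neg	18591-19809	19497-19532	19349-19356	19156-19232	18687-18833	18603-18611	true
S. paradoxus	CP020294.1	pos	307733-308897	308010-308045	308154-308161	308281-308353	308660-308803	308878-308886	true
S. cerevisiae	NC_001134.8	pos	307597-308757	307880-307914	308057-308064	308185-308256	308563-308682	308737-308746	true
S. pastorianus	AZCJ01000004.1	neg	478773-479970	479664-479718	479512-479520	479340-479417	478866-479012	478785-478793	true
S. cer. x S. kud.	AGVY01000004.1	pos	284183-285344	284465-284501	284645-284655	284772-284843	285150-285269	285325-285333	false
S. bayanus	AACG02000058.1	pos	58142-59362	58418-58472	58613-58620	58723-58799	59125-59270	59343-59351	true
S. sp. 'boulardii'	CM003558.1	pos	287536-288696	287818-287854	287998-288008	288124-288195	288502-288621	288677-288685	false
S. sp. M14	MVPU01000005.1	neg	473800-474997	474691-474745	474537-474547	474368-474444	473894-474038	473812-473820	false
S. cariocanus	AY639010.1	pos	1-1163	278-313	424-434	549-621	928-1072	1147-1155	true
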