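herbs	target_name	target_symbol	known_drug	indication	target_class
Radix Aconiti	Nuclear factor NF-kappa-B	NFKB2	Curaxin CBLC102; GMX1777; PG-490-88; Sulfasalizine; Tyloxapol;	rheumatoid arthritis	Clinical trial target
Radix Astragali	Transcription factor AP-1	JUN	T-5224	rheumatoid arthritis	Clinical trial target
Radix Aconiti	Metabotropic glutamate receptor 1	GRM1	AZD-9272; AZD8529; PF-1913539;	pain	Clinical trial target
Radix Astragali/Radix Aconiti	T-cell surface glycoprotein CD4	CD4	Blinatumomab;Anti-CD4	rheumatoid arthritis	Clinical trial target
Radix Aconiti	Beta-2 nAChR	CHRNB2	ABT-894	pain	Discontinued target
Radix Aconiti	Muscarinic acetylcholine receptor M1	CHRM1	Benztropine; Biperiden; Clidinium; Cycrimine; Darotropium; Darotropium + 642444; Dicyclomine; Ethopropazine; GSK1034702; GSK573719; GSK961081; Glycopyrrolate; Oxyphenonium; Pirenzepine; Propantheline; Revatropate; Sabcomeline hydrochloride; Talsaclidine fumarate; Talsaclidine isomer; Trihexyphenidyl; Xanomeline tartrate;	pain	Successful target
Radix Aconiti	Muscarinic acetylcholine receptor M3	CHRM3	Cevimeline; Darifenacin; Diphemanil Methylsulfate; LAS-34273; Oxybutynin; Revatropate; Solifenacin; Succinylcholine; Tiotropium; Tolterodine;	pain	Successful target
Raidix Paeoniae Alba/Herba Ephedrae	Prostaglandin G/H synthase 1	PTGS1	Suprofen; Salsalate	rheumatoid arthritis and osteoarthritis	Successful target
Raidix Paeoniae Alba/Herba Ephedrae	COX-2	PTGS2	Tolmetin;Tiaprofenic acid	pain and rheumatoid arthritis	Successful target
Radix Glycytthizae/Radix Astragali/Radix Aconiti	Aldose reductase	AKR1B1	Zenarestat;Sulindac	rheumatoid arthritis	Successful target
Radix Aconiti	Mu-type opioid receptor	OPRM1	Alfentanil; Alvimopan; Anileridine; Buprenex; Buprenorphine; Diphenoxylate; Fentanyl; GNTI; GSK1521498; LY-25582; Levomethadyl Acetate; Methadyl Acetate; Methylnaltrexone; Naloxone; Oxymorphone; Remifentanil; TD-1211; Tramadol ER;	pain	Successful target
Radix Aconiti	Kappa-type opioid receptor	OPRK1	Asimadoline; Dezocine; GNTI;	pain	Successful target
Radix Aconiti	Delta-type opioid receptor	OPRD1	BIO-306; Butorphanol; Codeine; Divers drug; Hydrocodone; Hydromorphone; Loperamide; Nalbuphine; Naltrexone; Oxycodone;	pain	Successful target
Radix Aconiti	Voltage-gated sodium channel subunit alpha Nav1.8	SCN10A	SPI-860; Tetracaine	pain	Successful target
Radix Aconiti	Tachykinin 1 receptor	TACR1	AZD2624; Aprepitant; CS-003; Casopitant; DA-5018; DNK-333; Ezlopitant; GSK 679769; GSK1144814; GSK424887; L-759274; Orvepitant; R 673; SLV-317; SLV-323; TAK-637; Vestipitant; Zunrisa/Rezonic;	pain	Successful target
Raidix Paeoniae Alba/Radix Glycytthizae/Radix Astragali/Herba Ephedrae/Radix Aconiti	Bile acid receptor	NR1H4	Guggulsterone	osteoarthritis	Successful target
Radix Astragali/Herba Ephedrae/Radix Aconiti	Glucocorticoid receptor	NR3C1	Amcinonide; Betamethasone; Budesonide; Dexamethasone; Flunisolide; Fluorometholone; Fluticasone; Fluticasone Propionate; GW685698X; GW870086X; ISIS-GCCRrx; Loteprednol Etabonate; Medrysone; Methylprednisolone; Mometasone; ORG 34517/34850; Prednisone;	rheumatoid arthritis	Successful target
Radix Aconiti	Cannabinoid receptor 1	CNR1	AVE1625; AZD1175; AZD1704; AZD1940; AZD2207; CB1 antagonist; CBD cannabis derivative; CP-945598; Dianicline+rimonabant; JD-5037; KDS-2000; Marinol; Rimonabant; Rimonbant; SLV-319; TM38837; Taranabant; Tebipenem; ZY01;	pain	Successful target
Radix Aconiti	Neuronal acetylcholine receptor subunit alpha-2	CHRNA2	Carbachol; Decamethonium; Doxacurium chloride; Levallorphan; Metocurine; Metocurine Iodide; Mivacurium; Pipecuronium; Rocuronium; Tubocurarine; Vecuronium;	pain	Successful target
Radix Aconiti	Interleukin-1 beta	IL1B	Canakinumab; Celastrol; Gallium nitrate; Glucosamine; Ibudilast;	osteoarthritis	Successful target
Raidix Paeoniae Alba/Radix Glycytthizae/Herba Ephedrae	Tumor necrosis factor	TNF	Etanercept/Adalimumab/Infliximab/	rheumatoid arthritis	Successful target
Herba Ephedrae	Voltage-dependent N-type calcium channel subunit alpha-1B	CACNA1B	Cilnidipine; Ralfinamide; Ziconotide;	pain	Successful target
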