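accession	gene	protein_name	position	region	localization
Q9DCS9	Ndufb10	NADH dehydrogenase 1 beta subcomplex subunit 10	77	L	Mitochondria;Cytosol
Q9CRB9	Chchd3	MICOS complex subunit Mic19	183	L	Nucleus;Mitochondria;Cytosol
P10126	Eef1a1	Elongation factor 1-alpha 1	411	L	Nucleus;Cytosol;Plasm membrane
A0A1S6GWI0	Ndufa8	NADH dehydrogenase 1 alpha subcomplex subunit 8	70	L	Mitochondria;Cytosol
P17563	Selenbp1	Selenium-binding protein 1	8	L	Nucleus;Cytosol
Q91X72	Hpx	Hemopexin	230	M	Extracellular space
P18572	Bsg	Basigin	203	M	Cytosol;Endoplasmic reticulum;Plasma membrane
P29699	Ahsg	Alpha-2-HS-glycoprotein (Fetuin-A)	219	M	Cytosol;Golgi apparatus;Extracellular space
Q9CVE7	Cmc1	COX assembly mitochondrial protein	57	M	Mitochondria;Cytosol
O70423	Aoc3	Membrane primary amine oxidase	430	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Plasma membrane;Extracellular space
Q8CGN5	Plin1	Perilipin-1	55	M	Cytosol;Endoplasmic reticulum
Q921I1	Tf	Serotransferrin	28	M	Extracellular space
Q921I1	Tf	Serotransferrin	67	M	Extracellular space
Q921I1	Tf	Serotransferrin	260	M	Extracellular space
Q921I1	Tf	Serotransferrin	363	M	Extracellular space
A0A1S6GWI4	Ndufs5	NADH dehydrogenase iron-sulfur protein 5	108	M	Mitochondria;Cytosol
Q546G4	Alb	Albumin	77	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Extracellular space
Q546G4	Alb	Albumin	86	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Extracellular space
Q546G4	Alb	Albumin	461	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Extracellular space
Q546G4	Alb	Albumin	462	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Extracellular space
Q546G4	Alb	Albumin	500	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Extracellular space
Q546G4	Alb	Albumin	501	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Extracellular space
Q546G4	Alb	Albumin	511	M	Cytosol;Endoplasmic reticulum;Golgi apparatus;Extracellular space
P10605	Ctsb	Cathepsin B	93	M	Mitochondria;Cytosol;Plasma membrane;Extracellular space
A0A1S6GWI0	Ndufa8	NADH dehydrogenase 1 alpha subcomplex subunit 8	144	M	Mitochondria;Cytosol
P56391	Cox6b1	Cytochrome c oxidase subunit 6B1	54	M	Mitochondria;Cytosol
Q8BMS1	Hadha	Trifunctional enzyme subunit alpha, mitochondrial	470	N	Mitochondria;Cytosol
Q7TPW6	Slc25a20	Mitochondrial carnitine/acylcarnitine translocase	155	N	Mitochondria;Cytosol
Q921I1	Tf	Serotransferrin	386	N	Extracellular space
Q921I1	Tf	Serotransferrin	395	N	Extracellular space
Q99KI0	Aco2	Aconitate hydratase, mitochondrial	126	N	Mitochondria;Cytosol
P51125	Cast	Calpastatin (Calpain inhibitor)	408	N	Cytosol;Endoplasmic reticulum
Q9D8N0	Eef1g	Elongation factor 1-gamma	266	N	Nucleus;Cytosol
Q8BH95	Echs1	Enoyl-CoA hydratase, mitochondrial	111	N	Mitochondria;Cytosol
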