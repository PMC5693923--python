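name	family	accession	fbg_start	fbg_end	table1_ridge	table1_triad	table1_ctail	table1_predicted	crystal_available
Tenascin-C	tenascin	P24821	1974	2201	7	+	+	yes	no
Tenascin-R	tenascin	Q92752	1128	1359	7	+	+	yes	no
Tenascin-W	tenascin	Q9UQP3	1060	1300	6	+	+	yes	no
Tenascin-X	tenascin	P22105	4013	4243	2	-	-	no	no
Angiopoietin-1	angiopoietin	Q15389	276	498	4	-	-	yes	yes
Angiopoietin-2	angiopoietin	O15123	271	496	4	-	-	yes	yes
Angiopoietin-4	angiopoietin	Q9Y264	277	503	1	-	-	no	no
Angiopoietin-like protein 1	angiopoietin-like	O95841	266	491	5	+	-	yes	no
Angiopoietin-like protein 2	angiopoietin-like	Q9UKU9	268	493	5	-	-	yes	no
Angiopoietin-like protein 3	angiopoietin-like	Q9Y5C1	235	460	0	-	-	no	no
Angiopoietin-like protein 4	angiopoietin-like	Q9BY76	184	406	0	-	-	no	no
Angiopoietin-like protein 5	angiopoietin-like	Q86XS5	163	388	2	-	-	no	no
Angiopoietin-like protein 6	angiopoietin-like	Q8NI99	245	470	5	-	-	yes	no
Angiopoietin-like protein 7	angiopoietin-like	O43827	124	346	2	-	-	no	no
FIBCD-1	other	Q8N539	236	461	2	-	-	no	yes
Fibrinogen alpha chain	fibrinogen chain	P02671	644	866	2	-	-	no	yes
Fibrinogen beta chain	fibrinogen chain	P02675	266	491	3	+	-	yes	yes
Fibrinogen gamma chain	fibrinogen chain	P02679	228	453	4	-	-	yes	yes
Fibrinogen-like protein 1	other	Q08830	87	312	5	-	-	yes	no
Fibroleukin	other	Q14314	214	439	5	-	-	yes	no
Ficolin-1	ficolin	O00602	101	326	4	-	-	yes	yes
Ficolin-2	ficolin	Q15485	88	313	2	-	-	no	yes
Ficolin-3	ficolin	O75636	74	299	2	-	-	no	yes
MFAP4	other	P55083	30	255	2	+	-	no	no
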