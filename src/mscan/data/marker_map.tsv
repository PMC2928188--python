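locus	chromosome	start_bp	end_bp
AGLA17	1	641402	641615
DIK4591	1	1704734	1705228
DIK1044	1	2829429	2829737
SOD1	1	2914373	2915349
DIK5019	1	3900549	3900808
BMS2321	1	10949260	10949302
BM1824	1	122531990	122532171
TGLA304	20	11460907	11460992
BMS1754	20	18439757	18439877
NRDIKM033	20	15598470	15598176
ILSTS068	20	21675187	21675451
TGLA126	20	21808628	21808745
BMS2461	20	25278607	25278662
BMS1128	20	26364064	26364112
BM713	20	26977228	26977280
DIK2695	20	30452613	30452786
TGLA153	20	31240022	31240154
GHRpromS	20	31023202	31023306
BMS2361	20	34597279	34597368
DIK4835	20	35915540	35916040
AGLA29	20	3842995	38843142
BMS117	20	40015465	40015564
UMBTL78	20	40177064	40177157
BM2113	2	88476	88616
INRA023	3	35576043	35576259
ETH10	5	55333999	55334220
ETH152	5	NA	NA
ILSTS006	7	86555402	86555693
HEL9	8	NA	NA
ETH225	9	8089454	8089601
MM12	9	NA	NA
ILSTS005	10	93304132	93304315
CSRM60	10	70549981	70550081
HEL13	11	NA	NA
INRA032	11	49569411	49569592
INRA037	11	70730695	70730819
INRA005	12	71751518	71751656
CSSM66	14	6128576	6128773
HEL1	15	NA	NA
SPS115	15	NA	NA
INRA035	16	62926476	62926577
TGLA53	16	22214785	22214925
ETH185	17	36598852	36599086
INRA063	18	37562469	37562645
TGLA227	18	60360145	60360234
ETH3	19	NA	NA
HEL5	21	11850292	11850455
TGLA122	21	50825795	50825936
HAUT24	22	45733839	45733962
BM1818	23	35634770	35635033
HAUT27	26	26396836	26396987
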