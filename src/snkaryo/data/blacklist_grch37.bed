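# Low-confidence regions excluded from binned analysis:
# telomeric gaps (10 kb) and centromeres, GRCh37 gap annotation.
1	0	10000
1	121535434	124535434
1	249240621	249250621
2	0	10000
2	92326171	95326171
2	243189373	243199373
3	0	10000
3	90504854	93504854
3	198012430	198022430
4	0	10000
4	49660117	52660117
4	191144276	191154276
5	0	10000
5	46405641	49405641
5	180905260	180915260
6	0	10000
6	58830166	61830166
6	171105067	171115067
7	0	10000
7	58054331	61054331
7	159128663	159138663
8	0	10000
8	43838887	46838887
8	146354022	146364022
9	0	10000
9	47367679	50367679
9	141203431	141213431
10	0	10000
10	39254935	42254935
10	135524747	135534747
11	0	10000
11	51644205	54644205
11	134996516	135006516
12	0	10000
12	34856694	37856694
12	133841895	133851895
13	0	10000
13	16000000	19000000
13	115159878	115169878
14	0	10000
14	16000000	19000000
14	107339540	107349540
15	0	10000
15	17000000	20000000
15	102521392	102531392
16	0	10000
16	35335801	38335801
16	90344753	90354753
17	0	10000
17	22263006	25263006
17	81185210	81195210
18	0	10000
18	15460898	18460898
18	78067248	78077248
19	0	10000
19	24681782	27681782
19	59118983	59128983
20	0	10000
20	26369569	29369569
20	63015520	63025520
21	0	10000
21	11288129	14288129
21	48119895	48129895
22	0	10000
22	13000000	16000000
22	51294566	51304566
X	0	10000
X	58632012	61632012
X	155260560	155270560
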