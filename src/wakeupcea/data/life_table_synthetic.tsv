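age	qx_male	qx_female
0.0	0.00022997355202769576	0.00022997355202769576
1.0	0.00023297285760814912	0.00023297285760814912
2.0	0.0002362720833539722	0.0002362720833539722
3.0	0.00023990121909944762	0.00023990121909944762
4.0	0.0002438932532037308	0.0002438932532037308
5.0	0.00024828447230762496	0.00024828447230762496
6.0	0.00025311479104483947	0.00025311479104483947
7.0	0.0002584281147005596	0.0002584281147005596
8.0	0.00026427273810647467	0.00026427273810647467
9.0	0.0002707017843883719	0.0002707017843883719
10.0	0.0002777736875465564	0.0002777736875465564
11.0	0.0002855527232413779	0.0002855527232413779
12.0	0.0002941095925933501	0.0002941095925933501
13.0	0.0003035220642871872	0.0003035220642871872
14.0	0.00031387568079355166	0.00031387568079355166
15.0	0.00032526453510006714	0.00032526453510006714
16.0	0.0003377921249798632	0.0003377921249798632
17.0	0.0003515722925223619	0.0003515722925223619
18.0	0.0003667302574187348	0.0003667302574187348
19.0	0.0003834037533342327	0.0003834037533342327
20.0	0.0004017442776272917	0.0004017442776272917
21.0	0.0004219184656880648	0.0004219184656880648
22.0	0.0004441096022835822	0.0004441096022835822
23.0	0.00046851928352342753	0.00046851928352342753
24.0	0.000495369244395305	0.000495369244395305
25.0	0.00052490336830191	0.00052490336830191
26.0	0.0005573898966353408	0.0005573898966353408
27.0	0.0005931238582056464	0.0005931238582056464
28.0	0.0006324297402742207	0.0006324297402742207
29.0	0.0006756644250730526	0.0006756644250730526
30.0	0.0007232204180186441	0.0007232204180186441
31.0	0.0007755293963808141	0.0007755293963808141
32.0	0.000833066109952596	0.000833066109952596
33.0	0.0008963526683245515	0.0008963526683245515
34.0	0.0009659632526937134	0.0009659632526937134
35.0	0.0010425292937851216	0.0010425292937851216
36.0	0.0011267451614318524	0.0011267451614318524
37.0	0.001219374415696639	0.001219374415696639
38.0	0.0013212566741332976	0.0013212566741332976
39.0	0.0014333151549239531	0.0014333151549239531
40.0	0.0015565649612057086	0.0015565649612057086
41.0	0.0016921221779597762	0.0016921221779597762
42.0	0.0018412138593957295	0.0018412138593957295
43.0	0.0020051889918659693	0.0020051889918659693
44.0	0.0021855305250085832	0.0021855305250085832
45.0	0.002383868572073511	0.002383868572073511
46.0	0.002601994889260717	0.002601994889260717
47.0	0.0028418787534030265	0.0028418787534030265
48.0	0.003105684367474937	0.003105684367474937
49.0	0.003395789934203197	0.003395789934203197
50.0	0.003714808549485804	0.003714808549485804
51.0	0.004065611079355214	0.004065611079355214
52.0	0.004451351196816056	0.004451351196816056
53.0	0.004875492767956735	0.004875492767956735
54.0	0.005341839790175218	0.005341839790175218
55.0	0.005854569099014606	0.005854569099014606
56.0	0.006418266073776935	0.006418266073776935
57.0	0.007037963585484475	0.007037963585484475
58.0	0.007719184443558791	0.007719184443558791
59.0	0.00846798760931533	0.00846798760931533
60.0	0.009291018454474886	0.009291018454474886
61.0	0.01019556335063887	0.01019556335063887
62.0	0.011189608880193602	0.011189608880193602
63.0	0.012281905959274142	0.012281905959274142
64.0	0.013482039157899028	0.013482039157899028
65.0	0.01480050148951062	0.01480050148951062
66.0	0.01624877491992227	0.01624877491992227
67.0	0.017839416811643583	0.017839416811643583
68.0	0.019586152470804752	0.019586152470804752
69.0	0.021503973896925044	0.021503973896925044
70.0	0.023609244746406133	0.023609244746406133
71.0	0.025919811403926962	0.025919811403926962
72.0	0.028455119906088844	0.028455119906088844
73.0	0.031236338271889985	0.031236338271889985
74.0	0.034286483557049996	0.034286483557049996
75.0	0.03763055265476789	0.03763055265476789
76.0	0.04129565550386949	0.04129565550386949
77.0	0.04531114892483468	0.04531114892483468
78.0	0.04970876877195873	0.04970876877195873
79.0	0.05452275745175761	0.05452275745175761
80.0	0.05978998309857941	0.05978998309857941
81.0	0.06555004580252854	0.06555004580252854
82.0	0.07184536523664209	0.07184536523664209
83.0	0.07872124281516102	0.07872124281516102
84.0	0.08622589012053106	0.08622589012053106
85.0	0.09441041375559855	0.09441041375559855
86.0	0.10332874500847855	0.10332874500847855
87.0	0.11303750077039454	0.11303750077039454
88.0	0.12359576004610806	0.12359576004610806
89.0	0.13506473818790166	0.13506473818790166
90.0	0.14750733874107613	0.14750733874107613
91.0	0.16098756062200237	0.16098756062200237
92.0	0.17556973641653661	0.17556973641653661
93.0	0.1913175761034872	0.1913175761034872
94.0	0.20829298976271882	0.20829298976271882
95.0	0.2265546631923876	0.2265546631923876
96.0	0.2461563623019447	0.2461563623019447
97.0	0.26714494623654317	0.26714494623654317
98.0	0.28955807609606476	0.28955807609606476
99.0	0.31342161659924606	0.31342161659924606
100.0	0.33874674292908846	0.33874674292908846
101.0	0.36552678509732306	0.36552678509732306
102.0	0.3937338682034741	0.3937338682034741
103.0	0.42331543941814453	0.42331543941814453
104.0	0.45419081143102635	0.45419081143102635
105.0	0.4862478968113537	0.4862478968113537
106.0	0.5193403565502767	0.5193403565502767
107.0	0.5532854359258403	0.5532854359258403
108.0	0.587862806939746	0.587862806939746
109.0	0.6228147720677688	0.6228147720677688
110.0	1.0	1.0
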