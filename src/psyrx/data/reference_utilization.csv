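n,drug,atc,route,form,ddd_mg,median_pdd,mean_pdd,ci_low,ci_high,ratio
17,Amisulpride,N05AL05,oral,standard,400,800,811.76,652.4,971.1,2.03
37,Aripiprazole,N05AX12,oral,standard,15,15,20.54,16.7,24.4,1.37
25,Asenapine,N05AH05,oral,standard,20,10,14.4,11.3,17.5,0.72
11,Clotiapine,N05AH06,oral,standard,80,40,35.45,24.4,46.5,0.44
11,Clozapine,N05AH02,oral,standard,300,350,345.45,284.2,406.7,1.15
3,Fluphenazine,N05AB02,injectable,long_acting,1,0.89,1.19,0.61,1.78,1.19
7,Haloperidol,N05AD01,oral,standard,8,5,7.63,2.4,12.9,0.95
3,Levomepromazine,N05AA01,oral,standard,300,50,58.33,42.0,74.7,0.19
36,Olanzapine,N05AH03,oral,standard,10,10,15.76,12.5,19.1,1.58
22,Paliperidone,N05AX13,oral,standard,6,10.5,11.59,9.5,13.7,1.93
63,Long-acting paliperidone,N05AX13,injectable,long_acting,2.5,3.57,4.79,4.34,5.24,1.92
38,Quetiapine,N05AH04,oral,standard,400,150,228.29,153.5,303.1,0.57
66,Risperidone,N05AX08,oral,standard,5,6,7.61,6.5,8.7,1.52
1,Long-acting risperidone,N05AX08,injectable,long_acting,2.7,7.14,7.14,7.14,7.14,2.64
10,Tiapride,N05AL03,oral,standard,400,300,290,244.3,335.7,0.73
1,Ziprasidone,N05AE04,oral,standard,80,120,120,120.0,120.0,1.50
2,Zuclopenthixol acufase,N05AF05,injectable,standard,30,25,25,25,25,0.83
12,Zuclopenthixol depot,N05AF05,injectable,long_acting,15,9.5,10.3,8.8,11.9,0.69
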