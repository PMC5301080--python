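atc,name,route,form,ddd_mg
N05AL05,Amisulpride,oral,standard,400
N05AX12,Aripiprazole,oral,standard,15
N05AH05,Asenapine,oral,standard,20
N05AH06,Clotiapine,oral,standard,80
N05AH02,Clozapine,oral,standard,300
N05AB02,Fluphenazine,injectable,long_acting,1
N05AD01,Haloperidol,oral,standard,8
N05AA01,Levomepromazine,oral,standard,300
N05AH03,Olanzapine,oral,standard,10
N05AX13,Paliperidone,oral,standard,6
N05AX13,Long-acting paliperidone,injectable,long_acting,2.5
N05AH04,Quetiapine,oral,standard,400
N05AX08,Risperidone,oral,standard,5
N05AX08,Long-acting risperidone,injectable,long_acting,2.7
N05AL03,Tiapride,oral,standard,400
N05AL03,Tiapride injectable,injectable,standard,400
N05AE04,Ziprasidone,oral,standard,80
N05AF05,Zuclopenthixol acufase,injectable,standard,30
N05AF05,Zuclopenthixol depot,injectable,long_acting,15
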