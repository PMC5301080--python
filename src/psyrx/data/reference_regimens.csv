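stratum,kind,categories,n,users,mono,poly
Substance use disorders,single,substance_use,16,8,6,2
Schizophrenia and other psychosis,single,schizophrenia_psychosis,101,101,62,39
Mood disorders,single,mood,69,51,33,18
Anxiety-related disorders,single,anxiety_related,24,5,4,1
Personality disorders,single,personality,21,12,10,2
Rest of the diagnoses,single,other,12,0,0,0
Organic disorders + mood disorders,comorbidity,organic;mood,5,2,1,1
Substance use disorders + schizophrenia and other psychosis,comorbidity,substance_use;schizophrenia_psychosis,10,9,4,5
Substance use disorders + mood disorders,comorbidity,substance_use;mood,6,6,4,2
Substance use disorders + personality disorders,comorbidity,substance_use;personality,7,9,4,5
Schizophrenia and other psychosis + personality disorders,comorbidity,schizophrenia_psychosis;personality,7,6,3,3
Mood disorders + personality disorders,comorbidity,mood;personality,6,4,2,2
Anxiety-related disorders + personality disorders,comorbidity,anxiety_related;personality,9,4,4,0
Other combinations,comorbidity,other_combinations,60,0,0,0
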