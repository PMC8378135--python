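drug,route,formulation,strength_mg,unit_cost,atypical,min_interval_days
chlorpromazine,oral,immediate,10.0,0.10,0,
haloperidol,oral,immediate,0.25,0.12,0,
loxapine,oral,immediate,2.0,0.25,0,
risperidone,oral,immediate,0.25,0.30,1,
olanzapine,oral,immediate,1.0,0.45,1,
quetiapine,oral,immediate,25.0,0.35,1,
aripiprazole,oral,immediate,1.0,0.80,1,
chlorpromazine,rectal,immediate,10.0,1.20,0,
haloperidol,injectable,immediate,1.0,3.50,0,
olanzapine,injectable,immediate,1.0,12.00,1,
haloperidol_decanoate,injectable,long_acting,50.0,22.00,0,28
flupentixol_decanoate,injectable,long_acting,20.0,18.00,0,14
risperidone_la,injectable,long_acting,12.5,95.00,1,14
paliperidone_palmitate,injectable,long_acting,75.0,210.00,1,28
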