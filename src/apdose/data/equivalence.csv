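drug,formulation,cpz_factor
chlorpromazine,immediate,1.0
risperidone,immediate,50.0
olanzapine,immediate,20.0
quetiapine,immediate,1.3333333333333333
aripiprazole,immediate,13.333333333333334
haloperidol,immediate,50.0
loxapine,immediate,10.0
haloperidol_decanoate,long_acting,56.0
flupentixol_decanoate,long_acting,70.0
risperidone_la,long_acting,56.0
paliperidone_palmitate,long_acting,56.0
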