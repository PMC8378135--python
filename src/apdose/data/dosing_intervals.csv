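drug,min_interval_days
haloperidol_decanoate,28
flupentixol_decanoate,14
risperidone_la,14
paliperidone_palmitate,28
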