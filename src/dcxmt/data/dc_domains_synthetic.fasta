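>NDC_synthetic stand-in NDC-like domain sequence (random, seeded)
LAEHSEALDAKSIVKNNSYVRDSFSAGSCSVLPIVQFHNSLVADVHYLIRVLSEKLRYKR
ENLETMFDNATYVLMSDFLINDVVGEKEGIIFMEAL
>CDC_synthetic stand-in CDC-like domain sequence (random, seeded)
VDQRKGILAARLMNQRQNTGSWALVSDRGSRRQCTGVFIADVPPDALLLGYIGGGSASVA
LAQLVSKEETAGMMLILYPNTPETSDDVMSG
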