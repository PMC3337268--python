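ISS-001
  toxlift

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
> <CASRN>
56-23-5

> <Canc>
3

> <ChemicalName>
carbon tetrachloride (synthetic toy record)

$$$$
ISS-002
  toxlift

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 S   0  0  0  0  0  0  0  0  0  0  0  0
M  END
> <CASRN>
69-72-7

> <Canc>
1

> <ChemicalName>
salicylic acid (synthetic toy record)

$$$$
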