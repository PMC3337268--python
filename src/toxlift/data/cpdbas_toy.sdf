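CPD-001
  toxlift

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
> <CASRN>
50-00-0

> <ActivityOutcome>
active

> <ChemicalName>
formaldehyde (synthetic toy record)

$$$$
CPD-002
  toxlift

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
M  END
> <CASRN>
62-53-3

> <ActivityOutcome>
active

> <ChemicalName>
aniline (synthetic toy record)

$$$$
CPD-003
  toxlift

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
M  END
> <CASRN>
64-17-5

> <ActivityOutcome>
inactive

> <ChemicalName>
ethanol (synthetic toy record)

$$$$
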