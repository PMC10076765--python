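# Argument Scheme for Alternative Options: why option O should be selected
# among a set of alternatives in circumstance C.
name: ASO
variables: [O, C]
premises:
  - "Given a set of alternative options"
  - "Given circumstance [C]"
  - "Option [O] does not cause complications in circumstance [C]"
conclusion: "[O] should be selected"
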