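# Argument Scheme for Alternative Clinical Options: the clinically
# specialized form of ASO, choosing a harmless treatment from the patient's
# record.
name: ASCO
variables: [R, Ft, T]
premises:
  - "Given a set of alternative treatments"
  - "Given the current state [R]"
  - "Considering the patient's fact [Ft] (subsumed in [R]), treatment [T] does not cause contraindication nor side effects"
conclusion: "[T] should be recommended"
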