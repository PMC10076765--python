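# Argument Scheme for Proposed Treatment: supports a treatment T given the
# patient's facts Ft and the goal G to be achieved.
name: ASPT
variables: [Ft, G, T]
premises:
  - "Given the patient's fact [Ft]"
  - "In order to realize goal [G]"
  - "Treatment [T] promotes goal [G]"
conclusion: "Treatment [T] should be considered"
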