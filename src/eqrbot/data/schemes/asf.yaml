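# Argument Scheme for Relevant Field of Expertise: why field F is the most
# relevant to the current state R and goal G.
name: ASF
variables: [F, R, G]
premises:
  - "Given a set of disciplinary fields of expertise"
  - "Given the current state [R]"
  - "Given a goal to achieve [G]"
  - "[F] yields more connections, with respect to [R] and [G], than any other fields"
conclusion: "[F] should be considered the most relevant disciplinary field"
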