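# Explanation-Question-Response scheme: practical reasoning merged with
# reasoning from expert opinion.  [Var] marks a substitution placeholder.
name: EQR
variables: [R, E, F, alpha, S, A, v]
premises:
  - "In the current state [R]"
  - "acting upon [alpha] (from an expert [E] in a field [F])"
  - "will result in a new state [S]"
  - "which will make proposition [A] true (alternatively, false)"
  - "which will promote some value [v]"
conclusion: "Acting upon the opinion [alpha] should make proposition [A] true (false) and entail value [v]"
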