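# Argument Scheme for Expert Reliability: why one source dominates the
# available set of knowledgeable experts.
name: ASEXP
variables: [E]
premises:
  - "Given a set of knowledgeable experts"
  - "[E] is more trustworthy and knowledgeable than any other experts"
conclusion: "[E] should be considered the most reliable expert"
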