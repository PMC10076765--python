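# Critical-question trigger table for the EQR scheme.
#
# Each entry compiles one critical question into a closed-world check over
# knowledge-base facts.  Pattern variables whose lowercased name equals a
# scheme variable (E, F, A, R, S, V -> v, Alpha -> alpha) are bound to the
# instance's binding (the element id, as a constant); any other uppercase
# variable (P, E2, ...) is existentially quantified.
#
# Modes:
#   unless         - the question attacks the instance unless the conjunction
#                    of `requires` patterns is satisfiable in the KB
#   fires_if       - the question attacks iff the `fires_if` conjunction is
#                    satisfiable
#   alternatives   - never attacks: alternative opinions yield alternative
#                    scheme instances instead of counter-arguments
#   negative_value - attacks iff the bound value carries a negative polarity
#                    tag in the ontology
#
# A fact  cq_answered(<atom>, <opinion id>)  records that the question has
# been answered for that opinion; it generates a defeater of the
# counter-argument.
scheme: EQR
answer_predicate: cq_answered
questions:
  - id: EQR.CQ1
    atom: eqr_cq1
    text: "Is E the most knowledgeable expert source?"
    mode: unless
    requires: ["most_knowledgeable(E)"]
  - id: EQR.CQ2
    atom: eqr_cq2
    text: "Is E trustworthy?"
    mode: unless
    requires: ["trustworthy(E)"]
  - id: EQR.CQ3
    atom: eqr_cq3
    text: "Is E an expert in the field F that alpha is in?"
    mode: unless
    requires: ["expert_in(E, F)", "opinion_field(Alpha, F)"]
  - id: EQR.CQ4
    atom: eqr_cq4
    text: "Would acting upon alpha imply A (or not A)?"
    mode: unless
    requires: ["implies(Alpha, A)"]
  - id: EQR.CQ5
    atom: eqr_cq5
    text: "Are there alternative experts' opinions that can be acted upon to imply A (or not A)?"
    mode: alternatives
  - id: EQR.CQ6
    atom: eqr_cq6
    text: "Would acting upon alpha entail contradictory propositions?"
    mode: fires_if
    fires_if: ["entails(Alpha, P)", "entails(Alpha, neg(P))"]
  - id: EQR.CQ7
    atom: eqr_cq7
    text: "Is A consistent with what other experts assert?"
    mode: fires_if
    fires_if: ["asserts(E2, neg(A))"]
  - id: EQR.CQ8
    atom: eqr_cq8
    text: "Is alpha based on the (facts expressed by) state R?"
    mode: unless
    requires: ["based_on(Alpha, R)"]
  - id: EQR.CQ9
    atom: eqr_cq9
    text: "Is F the most relevant disciplinary field to A given the (facts expressed by) state R?"
    mode: unless
    requires: ["most_relevant(F)"]
  - id: EQR.CQ10
    atom: eqr_cq10
    text: "Would acting upon alpha promote a negative value?"
    mode: negative_value
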