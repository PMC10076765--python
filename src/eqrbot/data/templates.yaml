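# Explanation templates, one per scheme.  [Var] placeholders are filled
# with the bound element's natural-language text.  The EQR text follows the
# COVID-19 worked example; the remaining texts are this package's own
# renderings built from each scheme's premises and conclusion.
- scheme: EQR
  txt: "Given [R], the expertise of [E] in the field of [F] indicates [alpha] as an effective treatment. This should lead to [S] which will bolster the goal of [A] and promote [v]."
- scheme: ASPT
  txt: "Given the patient's fact [Ft], and in order to realize the goal of [G], treatment [T] should be considered."
- scheme: ASEXP
  txt: "Among the available set of knowledgeable experts, [E] is more trustworthy and knowledgeable than any other experts, and is therefore considered the most reliable expert informing this recommendation."
- scheme: ASF
  txt: "Among the disciplinary fields of expertise, and given [R] together with the goal of [G], [F] yields more connections than any other fields and is therefore the most relevant field for this recommendation."
- scheme: ASO
  txt: "Among the set of alternative options, and given circumstance [C], option [O] does not cause complications and should be selected."
- scheme: ASCO
  txt: "Among the set of alternative treatments compatible with [R], and considering the patient's fact [Ft], [T] does not cause contraindication nor side effects; [T] is therefore the treatment recommended."
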