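# eqrbot

Argument-scheme explanations for clinical decision support: a reasoning
engine that instantiates clinical argument schemes from a patient
knowledge base, evaluates them as a Dung argumentation framework, renders
the acceptable instantiations as natural-language explanations, and
answers free-text follow-up questions with a bag-of-words retrieval
chatbot.

The package is aimed at researchers in computational argumentation and
explainable clinical decision support who need a self-contained,
reproducible implementation of scheme-based explanation delivery — no
external solver, no language model, no network access.

## The model

**Abstract argumentation.** A framework is a pair AF = ⟨AR, attacks⟩ with
attacks ⊆ AR × AR. A set S ⊆ AR is *conflict-free* if no member attacks
another; an argument X is *acceptable w.r.t.* S if every attacker of X is
attacked by some member of S; S is *admissible* if it is conflict-free and
each member is acceptable w.r.t. S; a complete extension additionally
contains every argument acceptable w.r.t. it. The least complete extension
is the *grounded* extension (the engine's default — unique and maximally
cautious); the maximal complete extensions are the *preferred* ones.
`eqrbot.af_core` implements all of these with deterministic enumeration
order, and `eqrbot.oracle` re-derives them by brute force over all 2^n
subsets as an independent cross-check.

**Argument schemes.** A scheme is a premise/conclusion template over a
variable set, AS = ⟨Prem, Con, Var⟩. Six clinical schemes ship as data
files: EQR (the central scheme — the consequences of acting upon an expert
opinion α from expert E in field F, moving state R to state S, making
proposition A true and promoting value v), ASPT (proposed treatment),
ASEXP (most reliable expert), ASF (most relevant field), ASO and ASCO
(alternative / alternative clinical options). A proposed-treatment
instance embeds into EQR by mapping T → α, Ft → R and G → A.

**Critical questions as attacks.** Each of the ten EQR critical questions
(is E trustworthy? is E an expert in F? would acting on α entail
contradictions? …) is compiled to a closed-world check over knowledge-base
facts (`data/cq_triggers.yaml`). A triggered question becomes a
counter-argument attacking the instance; a `cq_answered(cq, opinion)` fact
generates a defeater reinstating it. An instance is *acceptable* iff its
argument is accepted under the configured semantics, and only acceptable
instances may back an explanation.

**Retrieval chatbot.** Stored explanations and user queries are reduced to
token bags (tokenize → stop-word removal → lemmatize, all data-file
driven). A query is a (context, request) pair; the double-layer matcher
scores an entry as

    score = Σ_t min(c[t], text[t] + tags[t]) + Σ_t min(r[t], text[t])

and the first strictly-best entry (the initial explanation excluded) is
returned, with a canned "contact a healthcare professional" fallback when
nothing overlaps.

## Worked example

The packaged scenario is a pregnant patient with fever and headache due to
COVID-19. From the facts `current_state(fever, headache, COVID19)` and
`condition(pregnancy)` a guideline rule derives `recommend(paracetamol)`;
the pipeline instantiates ASPT, embeds it into EQR, finds all ten critical
questions rebutted, and accepts four instances (EQR, ASEXP, ASF, ASCO).

```sh
eqrbot demo --scenario frida
```

prints the session, beginning:

```
[bot] Given the patient's previous health record and the current fever and
headache (due to COVID-19), the expertise of the NICE guidelines in the
field of medical management of COVID-19 indicates the administering of
paracetamol as an effective treatment. This should lead to the reduction
of fever and headache which will bolster the goal of controlling the
negative effect of the COVID-19 virus and promote the patient's wellbeing.
[bot] Are you satisfied with this explanation?
[user] no
[bot] Would you please specify the context of your explanation request?
[user] expert reliability
[bot] What would you like to know?
[user] why NICE guidelines
[bot] Among the available set of knowledgeable experts, the NICE
guidelines is more trustworthy and knowledgeable than any other experts,
and is therefore considered the most reliable expert informing this
recommendation.
```

The opening message is the rendered EQR explanation; the reply to the
follow-up is the ASEXP (expert-reliability) explanation retrieved by the
matcher, and the field and alternative-treatment follow-ups retrieve the
ASF and ASCO explanations the same way. The same pipeline is scriptable:

```sh
eqrbot evaluate --out repo.json          # knowledge base -> repository
eqrbot chat --repo repo.json --seed 1 --script turns.txt
```

From Python:

```python
from eqrbot import frida_scenario, run_pipeline, chat_session

result = run_pipeline(frida_scenario())
print(len(result.repository))            # 4 accepted explanations
log = chat_session(result.repository, seed=1, turns=["yes"])
```

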