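# Methods

This note records the model implemented by `eqrbot`, the design choices
made where the design was genuinely open, and what the packaged tests do
and do not demonstrate.

## Argumentation core

`af_core` implements abstract frameworks ⟨AR, attacks⟩ and the semantics
chain conflict-free → acceptable → admissible → complete → grounded /
preferred. Design points:

- **Algorithms.** The grounded extension is the least fixed point of the
  characteristic function F(S) = {x : every attacker of x is attacked by
  S}, iterated from ∅ (at most |AR| iterations). Complete extensions are
  found by depth-first enumeration of conflict-free sets with pruning,
  keeping those with F(S) = S; preferred extensions are the ⊆-maximal
  ones. Frameworks in this pipeline are small — one scheme instance plus
  its critical-question attackers — so exhaustive search *is* the
  production path, guarded by a configurable cap (default 20 arguments;
  a `CapacityError` beyond it).
- **Oracle.** `oracle.enumerate_semantics` re-derives every semantics by
  testing all 2^n subsets directly against the definitions, using bitmask
  arithmetic and sharing no code with the production path. The two routes
  are compared on seeded random frameworks (≤ 12 arguments, attack
  density 0.25, self-attacks allowed) in the tests and the acceptance
  script.
- **Determinism.** Arguments iterate in sorted-id order; extension lists
  are ordered by (size, sorted members). Self-attacking arguments are
  permitted and simply never appear in conflict-free sets.
- **Acceptance mode.** Skeptical/credulous status under grounded,
  complete or preferred semantics. The default for explanation
  acceptability is grounded + skeptical: acceptability must be a unique,
  cautious notion, and grounded is the only semantics that is a single
  extension by construction.

## Knowledge base

A deliberately small first-order dialect (facts, Horn rules, `%`
comments, one statement per line) parsed by a hand-written recursive
descent parser — conflict handling lives in the argumentation layer, so
negation-as-failure and full ASP constructs are intentionally absent.
Numerical/representation choices:

- **Variable rule.** A token is a variable iff its first character is its
  only uppercase one (`X`, `Goal`, `E2`); acronym-style constants
  (`COVID19`, `NICE`) stay constants. This keeps clinical acronyms usable
  as atoms without quoting.
- **Negation.** One level of classical `neg(·)` on terms, used by states'
  truth assignments and the contradictory-entailment question; rules are
  negation-free and must be safe (head variables occur in the body).
- **Saturation.** Naive forward chaining to the least fixed point;
  monotone, idempotent, capped at 10,000 derivations (Horn rules over a
  finite constant set always terminate; the cap guards pathological
  inputs).
- **Preferences.** `prefer(category, a, b)` facts per category
  (guideline, treatment, value); the transitive closure must be
  irreflexive. `preferred_element` returns a maximal candidate, breaking
  incomparability lexicographically so selection is deterministic.

## Schemes and critical questions

The six scheme templates ship as YAML data with `[Var]` placeholders;
instantiation is pure substitution of each bound element's
natural-language text. The proposed-treatment scheme embeds into EQR as
α ← T, R ← Ft (the patient facts are part of the current state; an
explicit R in the extra bindings overrides), A ← G.

The critical questions' *text* is fixed, but nothing fixes how each
question becomes a decidable check, so the compilation is this package's
own and ships as reviewable data (`data/cq_triggers.yaml`) rather than
code:

- CQ1/CQ2/CQ3/CQ4/CQ8/CQ9 are closed-world "unless" checks: the question
  attacks unless its rebuttal facts are present (e.g. CQ2 unless
  `trustworthy(E)`, CQ3 unless `expert_in(E, F)` ∧ `opinion_field(α, F)`).
- CQ6/CQ7 are positive triggers: CQ6 fires if `entails(α, P)` and
  `entails(α, neg(P))` are jointly satisfiable, CQ7 if some other expert
  asserts ¬A.
- CQ10 fires iff the bound value is tagged negative in the ontology.
- CQ5 (alternative opinions) never attacks: alternative opinions produce
  alternative EQR instances, not counter-arguments, so offering more
  options cannot defeat a recommendation.
- A fact `cq_answered(cq, opinion)` records an answered question and
  emits a defeater of the counter-argument, giving the standard
  reinstatement pattern (answer → question → instance).

Attack direction is always counter-argument → instance and defeater →
counter-argument. Under grounded semantics this makes acceptance monotone
in rebuttal/answer facts: adding a rebuttal can only remove or defeat
attackers, never create one.

Expert and field hierarchies are explicit ranking facts
(`more_reliable(E, E′)`, `more_relevant(F, F′)`, transitively closed):
the ASEXP/ASF conclusions require the bound element to dominate all
others, and a singleton set trivially dominates. The auxiliary schemes
(ASEXP/ASF/ASO/ASCO) carry no critical questions of their own here; their
instances attach as supporting explanations, not as attackable targets.

## Explanations

One template per scheme (shipped data). Rendering substitutes binding
texts into the template, preserving all other characters exactly, and is
refused for any instance that is not accepted — no output of the chatbot
is ever backed by a defeated argument. Each repository entry is tagged
with lowercase filtered tokens from its scheme name and its bound expert,
field and treatment/opinion texts; the tags are the "context designation"
signal for the matcher. The repository persists as JSON (rendered text,
tags, scheme, bindings) so a chat session can run without re-evaluation.
When several EQR explanations are acceptable they are equally good, and
the initial one is a seeded uniform choice.

## Chatbot

The NLP filter is tokenize (lowercase, split on non-alphanumeric runs,
drop 1-character tokens) → stop-word removal (shipped list of ~140
common English words) → lemmatization (shipped exception table, then
conservative plural-stripping rules). It is a pure function of its input
and the shipped data; it never influences the reasoning engine.

The matcher scores an entry by clipped term-frequency overlap on two
layers with equal weights λc = λr = 1:
score = Σ min(c[t], text[t]+tags[t]) + Σ min(r[t], text[t]).
The context layer sees the entry's tags as well as its text; the request
layer sees the text alone. Retrieval scans every entry except the initial
explanation in fixed repository order and keeps the first strict
improvement, so earlier entries win ties. A query sharing no token with
any entry yields a canned fallback (seeded choice among three responses,
each deferring to a healthcare professional) rather than an arbitrary
entry.

A session is: initial EQR explanation → (satisfaction? → context →
request → answer)* — the bot never emits an unprompted message, the
knowledge base is frozen for the session (new data requires a restart),
and the whole transcript is a deterministic function of (repository,
seed, scripted turns).

## Synthetic scenarios

`generate_scenario(seed, n_experts, n_fields, n_treatments, p)` emulates
the pipeline's inputs at configurable scale: a random ontology, one
treatment recommendation (hence one EQR instance) per treatment, and each
critical-question rebuttal fact included independently with probability
`p`. Defaults (3 experts, 3 fields, 5 treatments, p = 1) model a small
multi-guideline clinic in which every question is answerable; p = 1 makes
every instance acceptable, p = 0 leaves every instance attacked and
undefended. Premise texts come from a closed vocabulary with one unique
token per treatment ("remedyN"), so self-probe queries (an entry's own
tags as context, its own text as request) are collision-free by
construction — the retrieval soundness/completeness measurements exercise
the matcher's bookkeeping, not its robustness to paraphrase.

What the generator does **not** emulate: free-text paraphrase and typos,
vocabulary overlap between distinct recommendations, multi-morbidity
interactions between rules, or clinically realistic guideline content.
Passing the desk-scale retrieval checks therefore shows the algorithm is
sound and complete for collaborative users at repository sizes 10–100,
as claimed, not that matching is robust to adversarial or sloppy input.

The packaged clinical scenario (a pregnant COVID-19 patient) carries one
reconstructed guideline rule; the published guideline is prose, so the
Horn encoding and the auxiliary explanation texts are package fixtures.

## Problem sizes and runtime

Semantics cross-validation uses 200 frameworks of ≤ 12 arguments (the
oracle enumerates 4,096 subsets at n = 12; its hard cap is 16). Retrieval
measurements use 50 seeded repositories spanning 10–100 entries. The full
test suite runs in well under a minute; the acceptance script in about
half a minute on one CPU.

## Known limitations

- Critical-question triggers are this package's compilation of the
  questions' intent; other trigger tables are defensible, which is why
  the table is data, not code.
- Only grounded/complete/preferred semantics are provided (no stable,
  semi-stable or ideal semantics; no bipolar or weighted frameworks).
- The lemmatizer is a lookup table plus plural rules, not a full
  morphological analyzer; words outside the table lemmatize approximately.
- The chatbot has no intra-session memory: a follow-up referring to an
  earlier answer is matched like any other query.
- Rules are negation-free Horn clauses; defeasibility is expressed only
  through attacks, so knowledge requiring genuine nonmonotonic rule
  semantics must be remodeled as critical questions.
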