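% Frida scenario knowledge base (package fixture).
%
% Patient facts from the EHR: a pregnant patient with fever and headache
% caused by COVID-19.
current_state(fever, headache, COVID19).
condition(pregnancy).

% Guideline rule: reconstruction of the NICE-NG191 paracetamol guidance.
% The published guideline is prose; this Horn encoding is a fixture of the
% package, not a transcription.
recommend(paracetamol) :- current_state(fever, headache, COVID19), condition(pregnancy).

% Pipeline designations: the opinion acted upon per recommended treatment,
% the current state, and what each opinion aims at / promotes.
treatment_opinion(paracetamol, paracetamol_administering).
initial_state(covid_state).
aims_at(paracetamol_administering, covid_control).
promotes(paracetamol_administering, wellbeing).
patient_facts(frida_facts).

% Critical-question rebuttals for the EQR instantiation.
most_knowledgeable(nice).
trustworthy(nice).
expert_in(nice, covid_management).
opinion_field(paracetamol_administering, covid_management).
implies(paracetamol_administering, covid_control).
based_on(paracetamol_administering, covid_state).
most_relevant(covid_management).

% Expert and field hierarchies (results of the preliminary probing).
more_reliable(nice, nhs).
more_relevant(covid_management, general_medicine).

% Alternative treatments and their safety profile.
treatment(paracetamol).
treatment(ibuprofen).
contraindicated(ibuprofen, pregnancy).

% Stakeholder preferences.
prefer(guideline, nice, nhs).
prefer(treatment, paracetamol, ibuprofen).
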