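# Lemma table for the NLP filter: surface form <TAB> lemma.
# Looked up after stop-word removal; forms not listed fall back to the
# plural-stripping rules in eqrbot.textproc.
acted	act
acting	act
administered	administer
administering	administer
advised	advise
advising	advise
assumed	assume
assuming	assume
bolstered	bolster
bolstering	bolster
caused	cause
causing	cause
chose	choose
chosen	choose
considered	consider
considering	consider
contraindicated	contraindicate
controlled	control
controlling	control
entailed	entail
entailing	entail
gave	give
given	give
giving	give
indicated	indicate
indicating	indicate
informed	inform
informing	inform
led	lead
leading	lead
managed	manage
managing	manage
promoted	promote
promoting	promote
reasoned	reason
reasoning	reason
recommended	recommend
recommending	recommend
reliability	reliable
relieved	relieve
relieving	relieve
remedies	remedy
selected	select
selecting	select
suffered	suffer
suffering	suffer
treated	treat
treating	treat
trusted	trust
trusting	trust
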