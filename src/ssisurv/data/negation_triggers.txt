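# NegEx-style trigger list: <tag>TAB<trigger phrase>
# pre  = negation scope covers the 5 tokens after the trigger
# post = negation scope covers the 5 tokens before the trigger
# term = conjunction that terminates a scope
pre	no
pre	not
pre	without
pre	denies
pre	denied
pre	absence of
pre	negative for
pre	rules out
pre	ruled out
pre	ingen
pre	inga
pre	inget
pre	inte
pre	ej
pre	icke
pre	utan
pre	förnekar
post	unlikely
post	osannolik
post	osannolikt
post	utesluten
post	uteslutet
post	uteslutes
term	but
term	however
term	although
term	except
term	men
term	dock
term	förutom
term	trots
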