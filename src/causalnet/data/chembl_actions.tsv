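action_type	category
ACTIVATOR	1
AGONIST	1
PARTIAL AGONIST	1
POSITIVE ALLOSTERIC MODULATOR	1
POSITIVE MODULATOR	1
OPENER	1
ANTAGONIST	2
BLOCKER	2
INHIBITOR	2
ANTISENSE INHIBITOR	2
INVERSE AGONIST	2
NEGATIVE ALLOSTERIC MODULATOR	2
NEGATIVE MODULATOR	2
BINDING AGENT	3
MODULATOR	3
RELEASING AGENT	3
STABILISER	3
SUBSTRATE	3
OTHER	3
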