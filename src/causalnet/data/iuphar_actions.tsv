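actions	category
Activation	1
Agonist	1
Biased agonist	1
Full agonist	1
Partial agonist	1
Potentiation	1
Antagonist	2
Channel blocker	2
Feedback inhibition	2
Inhibition	2
Inverse agonist	2
Irreversible inhibition	2
Binding	3
Competitive	3
Mixed	3
Neutral	3
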