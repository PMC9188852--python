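phrase	category	exclusions
channel blocking activity	2
inhibit 50%	2
inhibiting	2
inhibitor	2
activation	1	inactivation
channel opening activity	1
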