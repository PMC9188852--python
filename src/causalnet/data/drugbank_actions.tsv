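action	category
activator	1
agonist	1
inducer	1
partial agonist	1
positive allosteric modulator	1
positive modulator	1
potentiator	1
stimulator	1
antagonist	2
antisense oligonucleotide	2
blocker	2
downregulator	2
inactivator	2
inhibitor	2
inverse agonist	2
negative modulator	2
suppressor	2
binder	3
binding	3
chelator	3
cofactor	3
ligand	3
modulator	3
other	3
regulator	3
substrate	3
unknown	3
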