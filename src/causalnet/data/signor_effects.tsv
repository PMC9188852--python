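effect	category
form complex	3
binding	3
unknown	3
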