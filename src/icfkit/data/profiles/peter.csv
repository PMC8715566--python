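code,qualifier
d410,.1
d4200,.2
d440,.4
d445,.3
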