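code,qualifier,section
d4153,.0,problem
d4154,.2,problem
d465,.3,problem
d850,.4,problem
e1151,+3,facilitator
e155,.3,barrier
e580,+2,facilitator
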