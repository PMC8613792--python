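rater,POP1,POP2,POP3,POP4,POP5,POP6,POR1,POR2,POR3,POR4,POR5,POR6,POR7
E1,5,3,4,4,4,5,5,5,5,5,5,4,5
E2,5,4,3,5,4,4,5,5,5,5,5,4,4
E3,5,4,3,5,4,5,5,4,5,5,5,4,5
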