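age,value
100,2.03353033022
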