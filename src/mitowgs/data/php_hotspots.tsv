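position
146
152
204
16093
16192
16311
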