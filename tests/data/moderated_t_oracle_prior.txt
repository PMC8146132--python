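d0 1.99838549117822 s02 0.454503727986729
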