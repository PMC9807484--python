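raw	canonical
mIR-103a-3p	miR-103a-3p
miR-311-3p	miR-311-3p
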