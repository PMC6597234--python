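year,fraction
2008,0.06
2016,0.16
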