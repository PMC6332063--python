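species_id,alpha,beta
pyrrole,3.0,
2a,1.2,12.2
2b,1.1,10.7
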