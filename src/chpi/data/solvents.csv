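solvent_id,alpha_s,beta_s
acetonitrile,1.7,5.1
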