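cluster_id	compound	is_psi	file
toyA_synthetic	toy-compound-A	true	toyA_synthetic.faa
toyB_synthetic	toy-compound-B	true	toyB_synthetic.faa
toyC_synthetic	toy-compound-C	false	toyC_synthetic.faa
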