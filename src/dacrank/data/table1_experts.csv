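expert_id,mu0,sigma0,gamma0
expert_1,2.15,0.09,0.78
expert_2,2.16,0.07,0.82
expert_3,1.97,0.11,0.82
expert_4,2.35,0.11,0.94
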