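row,col,kl_ratio,bf
expert_1,expert_1,1,1
expert_1,expert_2,0.50,0.82
expert_1,expert_3,0.25,25.42
expert_1,expert_4,7.63,0.32
expert_2,expert_1,2.00,1.22
expert_2,expert_2,1,1
expert_2,expert_3,0.50,31.13
expert_2,expert_4,15.23,0.40
expert_3,expert_1,4.03,0.04
expert_3,expert_2,2.02,0.03
expert_3,expert_3,1,1
expert_3,expert_4,30.75,0.01
expert_4,expert_1,0.13,3.09
expert_4,expert_2,0.07,2.52
expert_4,expert_3,0.03,78.54
expert_4,expert_4,1,1
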