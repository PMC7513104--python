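row_id,kl,dac,dac_rank,m,bf_Jd,bf_rank
expert_1,1.43,0.56,2,5.57e-68,0.21,3
expert_2,2.86,1.12,3,6.82e-68,0.17,2
expert_3,5.76,2.26,4,2.19e-69,5.31,4
expert_4,0.19,0.07,1,1.72e-67,0.07,1
benchmark,2.55,,,1.16e-68,,
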