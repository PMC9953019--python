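variable,f_coarse,f_medium,f_fine,p,gci12,gci23,asymptotic_ratio
TAWSS,0.6507,0.6523,0.6530,1.25533,0.093225,0.222779,1.0010
OSI,0.2209,0.2227,0.2231,2.11008,0.069600,0.301029,1.0019
RRT,5.0077,5.1355,5.1875,1.29873,0.857794,2.131632,1.0101
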