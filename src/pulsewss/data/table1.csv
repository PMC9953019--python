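case,inlet_radius_m,mean_re,max_re,alpha
2B,0.01148,452.0,2026.5,15.87
7A,0.01167,459.4,2060.0,16.13
14B,0.01168,459.8,2061.8,16.15
16A,0.01157,455.5,2042.4,16.00
31A,0.01157,455.5,2042.4,16.00
41B,0.01152,453.5,2033.5,15.93
63A,0.01145,450.8,2021.2,15.83
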