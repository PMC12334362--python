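quantity,1958,1980,1993,2009,2019
max_loop_weight,0.7729,0.7295,0.6954,0.7113,0.7896
required_s,0.019,0.022,0.006,0.008,0.026
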