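diameter_A,cyclic_n,rise_A,twist_deg
180,1,3.18,-161.1
200,2,5.75,34.4
215,1,2.52,130.2
235,3,6.97,28.3
250,1,2.10,-83.6
270,2,3.92,-78.0
280,3,5.64,22.9
290,4,6.92,21.2
305,1,1.64,-85.0
320,1,1.53,-140.3
365,3,3.95,-52.0
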