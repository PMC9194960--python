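sample_id	condition	dataset
N1	normal	GSE77459
N2	normal	GSE77459
N3	normal	GSE77459
N4	normal	GSE77459
N5	normal	GSE77459
N6	normal	GSE77459
P1	pulpitis	GSE77459
P2	pulpitis	GSE77459
P3	pulpitis	GSE77459
P4	pulpitis	GSE77459
P5	pulpitis	GSE77459
P6	pulpitis	GSE77459
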