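sample_id	condition	dataset
N1	normal	GSE92681
N2	normal	GSE92681
N3	normal	GSE92681
N4	normal	GSE92681
N5	normal	GSE92681
P1	pulpitis	GSE92681
P2	pulpitis	GSE92681
P3	pulpitis	GSE92681
P4	pulpitis	GSE92681
P5	pulpitis	GSE92681
P6	pulpitis	GSE92681
P7	pulpitis	GSE92681
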