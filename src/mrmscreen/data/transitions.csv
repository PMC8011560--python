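cl_homolog,precursor_mz,product_mz
1,188.0,152.0
2,222.0,152.0
3,258.0,186.0
4,291.9,222.0
5,325.0,255.9
6,359.8,289.9
7,393.8,323.9
8,429.7,259.8
9,463.7,393.8
10,497.7,427.9
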