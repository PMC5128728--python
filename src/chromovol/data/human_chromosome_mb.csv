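chromosome,length_mb
1,248.96
2,242.19
3,198.30
4,190.21
5,181.54
6,170.81
7,159.35
8,145.14
9,138.39
10,133.80
11,135.09
12,133.28
13,114.36
14,107.04
15,101.99
16,90.34
17,83.26
18,80.37
19,58.62
20,64.44
21,46.71
22,50.82
X,156.04
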