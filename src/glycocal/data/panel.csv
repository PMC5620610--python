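id,group,name,notation,reported_mw,approx
1,A,8-mer NAc,GlcNAc-(GlcA-GlcNAc)_3_-GlcA-pNP,1656,0
2,A,10-mer NAc,GlcNAc-(GlcA-GlcNAc)_4_-GlcA-pNP,2036,0
3,A,12-mer NAc,GlcNAc-(GlcA-GlcNAc)_5_-GlcA-pNP,2415,0
4,A,14-mer NAc,GlcNAc-(GlcA-GlcNAc)_6_-GlcA-pNP,2794,0
5,A,16-mer NAc,GlcNAc-(GlcA-GlcNAc)_7_-GlcA-pNP,3174,0
6,A,18-mer NAc,GlcNAc-(GlcA-GlcNAc)_8_-GlcA-pNP,3553,0
7,B,8-mer NS,GlcNS-(GlcA-GlcNS)_3_-GlcA-pNP,1808,0
8,B,10-mer NS,GlcNS-(GlcA-GlcNS)_4_-GlcA-pNP,2226,0
9,B,12-mer NS,GlcNS-(GlcA-GlcNS)_5_-GlcA-pNP,2643,0
10,B,14-mer NS,GlcNS-(GlcA-GlcNS)_6_-GlcA-pNP,3060,0
11,B,16-mer NS,GlcNS-(GlcA-GlcNS)_7_-GlcA-pNP,3478,0
12,B,18-mer NS,GlcNS-(GlcA-GlcNS)_8_-GlcA-pNP,3895,0
13,C,10-mer NS2S,GlcNS-GlcA-(GlcNS-IdoA2S)_3_-GlcNS-GlcA-pNP,2466,0
14,C,12-mer NS2S,GlcNS-GlcA-(GlcNS-IdoA2S)_4_-GlcNS-GlcA-pNP,2963,0
15,C,14-mer NS2S,GlcNS-GlcA-(GlcNS-IdoA2S)_5_-GlcNS-GlcA-pNP,3461,0
16,C,16-mer NS2S,GlcNS-GlcA-(GlcNS-IdoA2S)_6_-GlcNS-GlcA-pNP,3958,0
17,C,18-mer NS2S,GlcNS-GlcA-(GlcNS-IdoA2S)_7_-GlcNS-GlcA-pNP,4456,0
18,D,10-mer NS6S,GlcNS6S-(GlcA-GlcNS6S)_4_-GlcA-pNP,2626,0
19,D,12-mer NS6S,GlcNS6S-(GlcA-GlcNS6S)_5_-GlcA-pNP,3124,0
20,D,14-mer NS6S,GlcNS6S-(GlcA-GlcNS6S)_6_-GlcA-pNP,3621,0
21,D,16-mer NS6S,GlcNS6S-(GlcA-GlcNS6S)_7_-GlcA-pNP,4118,0
22,D,18-mer NS6S,GlcNS6S-(GlcA-GlcNS6S)_8_-GlcA-pNP,4616,0
23,E,8-mer NS6S2S,GlcNS6S-GlcA-(GlcNS6S-IdoA2S)_2_-GlcNS6S-GlcA-pNP,2289,0
24,E,12-mer NS6S2S,GlcNS6S-GlcA-(GlcNS6S-IdoA2S)_4_-GlcNS6S-GlcA-pNP,3444,0
25,E,14-mer NS6S2S,GlcNS6S-GlcA-(GlcNS6S-IdoA2S)_5_-GlcNS6S-GlcA-pNP,4021,0
26,E,16-mer NS6S2S,GlcNS6S-GlcA-(GlcNS6S-IdoA2S)_6_-GlcNS6S-GlcA-pNP,4599,0
27,E,18-mer NS6S2S,GlcNS6S-GlcA-(GlcNS6S-IdoA2S)_7_-GlcNS6S-GlcA-pNP,5176,0
28,F,dp4,"∆HexA,2S-GlcNS6S-IdoA2S-GlcNS6S",1200,1
29,F,dp6,"∆HexA,2S-GlcNS6S-(IdoA2S-GlcNS6S)_2_",1800,1
A1,G,USP A.1,,11000,0
A2,G,USP A.2,,5200,0
A3,G,USP A.3,,2250,0
A4,G,USP A.4,,1400,0
B1,G,USP B.1,,7750,0
B2,G,USP B.2,,3350,0
B3,G,USP B.3,,1800,0
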