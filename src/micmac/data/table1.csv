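case_id,diagnosis,sex,age,pmd,disease_score,concomitant,in_analysis
1,CTL,F,86,5.7,,,True
2,CTL,F,80,17.5,,,True
3,CTL,F,89,23.6,,Some senile plaques and NFTs,True
4,CTL,M,89,32.2,,,True
5,CTL,M,80,13.0,,Some senile plaques,True
6,CTL,F,83,35.7,,,True
7,CTL,F,95,23.7,,,True
8,CTL,M,85,26.7,,,True
9,CTL,M,83,16.8,,,True
10,CTL,M,89,31.9,,A1B1C1,True
11,CTL,F,55,21.1,,,True
12,DLB,M,70,24.5,Neo-cortical diffuse,Senile plaques and NFTs,True
13,DLB,M,89,17.0,Limbic transitional,Mixed AD,True
14,DLB,M,75,21.0,Neo-cortical,Senile plaques and NFTs,True
15,DLB,M,64,17.2,Neo-cortical,Senile plaques and NFTs,True
16,DLB,F,83,17.7,Neo-cortical,Senile plaques and NFTs,True
17,DLB,M,82,22.0,Neo-cortical diffuse,,True
18,DLB,F,81,8.6,Neo-cortical diffuse,,True
19,DLB,F,74,27.6,Neo-cortical,A2B2C0,True
20,DLB,M,91,85.0,Neo-cortical diffuse,Braak III/IV,False
21,AD,M,80,15.5,Braak IV,,True
22,AD,M,82,11.5,Braak IV,,True
23,AD,M,85,31.1,A2B3C2,,True
24,AD,F,83,25.0,A2B3C2,,True
25,AD,M,91,25.0,A2B3C2,,True
26,AD,F,96,26.5,Braak IV/V,,True
27,AD,M,87,21.7,A2B3C2,,True
28,AD,M,90,26.1,A3B2C3,,True
29,AD,F,87,17.0,A1B2C2,,True
30,AD,M,90,32.0,A2B2C3,,True
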