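# Synthetic stand-in table of pathogenic DCX missense mutations.
# Residue numbering: human DCX isoform 2 (360 aa). Constructed so the
# marginal counts match the published census (78 mutations, 73 in the
# DC domains over 65 unique sites, 33 NDC + 32 CDC, 5 outside); the
# individual sites and substitutions are NOT clinical records.
residue,wt_aa,mut_aa,domain
10,G,F,outside
25,H,P,outside
50,A,K,NDC
50,A,Q,NDC
53,R,E,NDC
53,R,M,NDC
56,N,F,NDC
56,N,G,NDC
59,D,H,NDC
59,D,P,NDC
62,C,I,NDC
62,C,S,NDC
65,Q,L,NDC
68,E,K,NDC
71,G,M,NDC
74,H,F,NDC
77,I,P,NDC
80,L,S,NDC
83,K,T,NDC
86,M,W,NDC
89,F,Y,NDC
92,P,V,NDC
95,S,A,NDC
98,T,R,NDC
101,W,N,NDC
104,Y,D,NDC
107,V,C,NDC
110,A,Q,NDC
113,R,E,NDC
116,N,G,NDC
119,D,H,NDC
122,C,I,NDC
125,Q,L,NDC
128,E,K,NDC
131,G,M,NDC
134,H,F,NDC
137,I,P,NDC
140,L,S,NDC
143,K,T,NDC
146,M,W,NDC
172,D,I,CDC
172,Q,T,CDC
174,C,L,CDC
174,E,W,CDC
176,G,Y,CDC
176,Q,K,CDC
178,E,M,CDC
180,G,F,CDC
182,H,P,CDC
184,I,S,CDC
186,L,T,CDC
188,K,W,CDC
190,M,Y,CDC
192,F,V,CDC
194,P,A,CDC
196,S,R,CDC
198,T,N,CDC
200,W,D,CDC
202,Y,C,CDC
204,V,Q,CDC
206,A,E,CDC
208,R,G,CDC
210,N,H,CDC
212,D,I,CDC
214,C,L,CDC
216,Q,K,CDC
218,E,M,CDC
220,G,F,CDC
222,H,P,CDC
224,I,S,CDC
226,L,T,CDC
228,K,W,CDC
230,M,Y,CDC
232,F,V,CDC
234,P,A,CDC
300,I,S,outside
320,L,T,outside
350,K,W,outside
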