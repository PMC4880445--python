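position_i,position_j,r_fret,r_fret_model,r_em_model,group
P+50T,P+17B,56,57,50.0,free
P-58B,P-15T,70,72,70.6,free
P-15T,B+17B,76,77,78.8,free
P-58B,P+17B,76,70,67.9,free
P-15T,P+17B,89,80,81.1,free
P+17B,B-15T,93,81,85.3,free
P+50T,P-58B,99,125,108.9,free
B-15T,B+17B,103,86,82.5,free
P-118T,B+17B,80,69,64.1,conflict_site3
P-118T,P-15T,82,77,95.3,conflict_site3
P-118T,B-15T,99,108,100.0,conflict_site3
P+79B,P-118T,56,56,41.4,conflict_site8
P+79B,B-15T,74,65,75.2,conflict_site8
P+79B,P-15T,96,109,81.3,conflict_site8
P+79B,P+17B,96,107,85.4,conflict_site8
P+79B,P-58B,108,158,124.8,conflict_site8
P+79B,B+17B,116,73,68.2,conflict_site8
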