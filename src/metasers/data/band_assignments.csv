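low_cm1,high_cm1,assignment
715,740,"Tryptophan, coenzyme A, nucleic acids"
810,830,Tyrosine
940,965,α-Helix backbone ν(C-Cα-N)
1025,1060,"C-N, C-C stretching of protein and lipids"
1200,1265,"Amide III proteins, nucleic acids U"
1300,1370,"CH2-CH2 of nucleic acids, Protein Backbone δ(CαH)"
1495,1530,Carotenoids polyene ν(C=C)
1545,1570,"Nucleic acids (guanine), amide II, Trp proteins"
1575,1630,"Trp, Tyr, and Phe Proteins"
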