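context	signature	genes
WOT	MET-gate	Cldn6;Cldn7;Sfn;Krt8;Krt18;Epcam
WOT	Generic stress	Mt1;Mt2;Hspa8;Hsp90aa1;Hsp90ab1;Dnaja1
WOT	Apoptosis/senescence	Peg3;Cdkn1a;Bax;Bbc3;Trp53inp1;Gadd45a;Igfbp7
Kidney	Stress/proteostasis	Ubc;Ubb;Hsp90aa1;Hsp90ab1;Dnaja1;Hspa8;Jun;Gclm;Gclc
Kidney	Apoptosis/senescence	Casp3;Bax;Bcl2;Bbc3;Cdkn1a;Trp53inp1;Gadd45a
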