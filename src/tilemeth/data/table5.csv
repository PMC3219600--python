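seg_id,chrom,start,stop,assay_id,mspji_relmeth,fspei_relmeth,confirmed,ibd,cis_trans
4,chr1,86899,87699,MDMR_40,-9.23,-9.14,Yes,,cis
36,chr1,19520608,19522008,MDMR_43,-2.84,-7.66,Yes,,
42,chr1,19982857,19984474,MDMR_82,-3.79,-5.22,Yes,,
94,chr1,39036362,39039562,MDMR_24,-5.14,-5.87,Yes,,trans
213,chr1,160563568,160563968,BDMR_22,2.73,2.44,Yes,,cis
215,chr1,162538673,162540073,MDMR_44,-7.81,-11.09,Yes,,
247,chr1,190761322,190762322,MDMR_27,-5.65,-10.1,Yes,,trans
710,chr2,144048581,144048981,BDMR_45,-1.38,-0.72,No,,
788,chr3,7683400,7686600,MDMR_73,-3.7,-8.04,Yes,Yes,cis
792,chr3,8346040,8348062,MDMR_74,-6.36,-9.79,Yes,Yes,cis
794,chr3,8357591,8358191,BDMR_78,3.76,9.4,Yes,Yes,
999,chr3,183380573,183381173,BDMR_3,-0.82,-0.17,No,,
1060,chr3,205814185,205816207,MDMR_41,-6.3,-13.2,Yes,,
1064,chr3,206677794,206678782,BDMR_48,1.9,3.34,Yes,,
1066,chr3,209258739,209259431,BDMR_51,1.31,3,Yes,,
1193,chr4,108425289,108425889,BDMR_79,-6.21,1.17,No,Yes,
1252,chr4,140005016,140005441,MDMR_1,-4.73,-3.93,Yes,,cis
1280,chr4,160954336,160955336,MDMR_37,-5.36,-9.87,Yes,,cis
1479,chr5,69250995,69252274,BDMR_49,5.58,4.69,Yes,,cis
1493,chr5,96853806,96854606,BDMR_53,3,1.64,Yes,Yes,cis
1603,chr6,60183875,60184275,MDMR_8,-4.9,-3.95,Yes,,
1697,chr6,161113703,161114709,MDMR_4,-4.34,-9.87,Yes,,
1840,chr7,150216544,150218384,BDMR_31,2.94,2.02,Yes,,
1895,chr8,97274412,97276412,MDMR_36,-3.58,-1.43,No,,
1938,chr8,143704696,143705542,MDMR_75,-5.34,-10.08,Yes,Yes,
1940,chr8,145875662,145877862,MDMR_76,-3.41,-2.52,Yes,Yes,cis
1946,chr8,151080956,151083158,MDMR_77,-1.34,ND,Yes,Yes,
1968,chr9,3855741,3856077,BDMR_62,2.84,2.9,Yes,,
2005,chr9,20864861,20865197,MDMR_13,-2.25,-1.99,Yes,,
2033,chr9,37257975,37258311,BDMR_59,2.52,-0.83,No,,
2178,chr9,116238414,116238750,BDMR_32,2.9,2.93,Yes,,
2209,chr9,145760392,145760896,BDMR_47,3.06,3.89,Yes,,cis
526,chr10,126586236,126586636,MDMR_38,-5.66,-6.09,Yes,,trans
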