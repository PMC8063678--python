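# Synthetic codon-usage snapshot in Kazusa layout for Escherichia coli (taxid 562).
# NOT data from the Kazusa database: counts are generated, for offline use.
# fields: [triplet] [frequency: per thousand] ([number])

AAA  84.4( 1862551)  AAC   1.9(   42500)  AAG   0.8(   17555)  AAU  67.0( 1478232)
ACA   7.1(  156654)  ACC   0.0(     376)  ACG   8.8(  194474)  ACU   0.5(   10836)
AGA   0.7(   15654)  AGC  11.0(  243189)  AGG   0.5(   11915)  AGU   3.0(   66731)
AUA   8.4(  185178)  AUC  36.3(  799760)  AUG  27.4(  604235)  AUU   5.2(  114524)
CAA  14.1(  311895)  CAC  14.6(  322441)  CAG  25.8(  569766)  CAU  15.9(  350870)
CCA   4.8(  106544)  CCC  13.1(  287864)  CCG  21.2(  467228)  CCU  40.7(  898743)
CGA   3.9(   86436)  CGC  20.1(  442952)  CGG   3.3(   71755)  CGU  12.2(  269526)
CUA  11.5(  254676)  CUC   3.3(   72792)  CUG   0.1(    2997)  CUU  12.9(  284990)
GAA  39.6(  872545)  GAC  27.6(  608545)  GAG  10.2(  224510)  GAU  38.9(  858091)
GCA  36.7(  809840)  GCC  10.3(  226095)  GCG   9.0(  199174)  GCU  18.4(  406567)
GGA   3.2(   70337)  GGC  13.1(  288938)  GGG   3.9(   85084)  GGU   0.3(    7413)
GUA   2.1(   45824)  GUC  11.9(  263205)  GUG   2.8(   61359)  GUU   3.6(   80497)
UAA   0.4(    8561)  UAC  28.5(  628552)  UAG   1.0(   21438)  UAU   0.7(   14341)
UCA   1.0(   22360)  UCC   4.5(   98167)  UCG   0.7(   15811)  UCU  57.5( 1268798)
UGA   0.0(      18)  UGC  18.3(  403216)  UGG  35.6(  784489)  UGU  50.2( 1106551)
UUA  45.0(  992864)  UUC   4.3(   93880)  UUG   1.3(   29765)  UUU  38.7(  853212)
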