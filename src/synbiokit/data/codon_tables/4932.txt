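# Synthetic codon-usage snapshot in Kazusa layout for Saccharomyces cerevisiae (taxid 4932).
# NOT data from the Kazusa database: counts are generated, for offline use.
# fields: [triplet] [frequency: per thousand] ([number])

AAA  15.2(  363522)  AAC  24.5(  584551)  AAG   2.4(   57780)  AAU  24.4(  582807)
ACA  13.2(  314696)  ACC   4.2(  100221)  ACG   5.8(  137340)  ACU   0.7(   17635)
AGA   1.5(   36451)  AGC   0.5(   11262)  AGG   0.2(    4682)  AGU   1.0(   24230)
AUA   8.9(  211315)  AUC  14.5(  345523)  AUG  50.4( 1201346)  AUU  56.5( 1347889)
CAA   5.0(  118468)  CAC  53.1( 1267901)  CAG  75.2( 1795374)  CAU  27.1(  646042)
CCA   8.6(  205622)  CCC  24.6(  586353)  CCG   1.1(   27403)  CCU   0.7(   16172)
CGA  23.6(  563372)  CGC   5.3(  125608)  CGG  19.4(  462432)  CGU   2.2(   53546)
CUA  12.5(  299389)  CUC  14.0(  333941)  CUG  10.5(  251205)  CUU   2.2(   51563)
GAA  14.8(  352576)  GAC  35.6(  849493)  GAG  56.1( 1338200)  GAU  22.4(  533341)
GCA  27.8(  664467)  GCC   3.1(   74115)  GCG   2.6(   63212)  GCU   6.0(  143724)
GGA  16.9(  402583)  GGC  24.4(  581386)  GGG   3.5(   83590)  GGU  15.6(  372363)
GUA  36.3(  866551)  GUC  21.1(  504079)  GUG  19.8(  473600)  GUU   5.9(  141367)
UAA   0.2(    4517)  UAC   3.8(   91731)  UAG   1.4(   33204)  UAU   7.3(  174040)
UCA   0.9(   22218)  UCC   0.7(   16888)  UCG   7.7(  184486)  UCU   1.3(   30972)
UGA   0.2(    5526)  UGC   8.2(  194975)  UGG  10.0(  239606)  UGU  20.2(  481090)
UUA  15.6(  372977)  UUC  52.3( 1247939)  UUG  18.4(  438181)  UUU  30.6(  730464)
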