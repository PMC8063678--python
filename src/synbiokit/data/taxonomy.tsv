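# organism name <TAB> NCBI taxonomy id (bundled subset)
Escherichia coli	562
Saccharomyces cerevisiae	4932
Bacillus subtilis	1423
Homo sapiens	9606
Komagataella pastoris	4922
Pseudomonas putida	303
Vibrio natriegens	691
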