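# GenBank feature key -> Sequence Ontology accession (editable)
# Reverse mapping uses the first key listed for each accession.
promoter	SO:0000167
RBS	SO:0000139
ribosome_binding_site	SO:0000139
CDS	SO:0000316
terminator	SO:0000141
rep_origin	SO:0000296
misc_feature	SO:0000110
gene	SO:0000704
operator	SO:0000057
primer_bind	SO:0005850
protein_bind	SO:0000410
5'UTR	SO:0000204
3'UTR	SO:0000205
mRNA	SO:0000234
tRNA	SO:0000253
rRNA	SO:0000252
source	SO:0000149
enhancer	SO:0000165
insulator	SO:0000627
polyA_signal	SO:0000551
sig_peptide	SO:0000418
stem_loop	SO:0000313
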