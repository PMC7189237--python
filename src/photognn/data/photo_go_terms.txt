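# Photosynthesis-specific GO term list (synthetic stand-in).
# A default working set of photosynthesis GO ids centred on GO:0015979 and
# its well-known descendant/related terms from the public Gene Ontology.
# Substitute your own curated list via the photo_go_terms config key.
GO:0015979
GO:0019684
GO:0019685
GO:0009765
GO:0009767
GO:0009768
GO:0009769
GO:0009772
GO:0009773
GO:0009521
GO:0009522
GO:0009523
GO:0009538
GO:0009539
GO:0009654
GO:0010207
GO:0042549
GO:0030076
GO:0016168
GO:0015977
GO:0010109
GO:0009853
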