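# Phylogeographic ancestry partition: components are tested in order and
# a record joins the first component containing its haplogroup.
# South Asian maternal ancestry is indexed by macro-haplogroup M excluding
# the (North/East African) M1 branch; sub-Saharan by the L clades outside
# M and N; West Eurasian by N-derived lineages plus M1.
id: phylogeo-default
other_label: other
components:
  - name: south_asian
    clades: ["M(×M1)"]
  - name: sub_saharan
    clades: [L]
  - name: west_eurasian
    clades: [N, M1]
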