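# Alternative ancestry partition: the M1a1 lineages, whose identical
# matches occur in North/East Africa as well as the Middle East, are read
# as African rather than West Eurasian. Same grammar as
# partition_rules.yaml; components are tested in order.
id: phylogeo-m1a1-african
other_label: other
components:
  - name: south_asian
    clades: ["M(×M1)"]
  - name: sub_saharan
    clades: [L, M1a1]
  - name: west_eurasian
    clades: [N, "M1(×M1a1)"]
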