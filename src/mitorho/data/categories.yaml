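# Display categories for haplogroup frequency tables.
# Each category lists clade expressions resolved against the haplogroup
# tree; the first matching category wins, "other" catches the rest
# (a paragroup for records not unambiguously assignable to any category).
id: romani-frequency-categories
other_label: other
categories:
  - name: M5a1b1a1
    clades: [M5a1b1a1]
  - name: "M(xM5a1b1a1)"
    clades: ["M(×M5a1b1a1)"]
  - name: U3
    clades: [U3]
  - name: H
    clades: [H]
  - name: "HV(xH)"
    clades: ["HV(×H)"]
  - name: U(xU3)
    clades: ["U(×U3)"]
  - name: L
    clades: [L]
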