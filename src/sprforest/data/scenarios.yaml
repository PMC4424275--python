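# The six study disturbance scenarios: fractions of the plot population
# affected and the tree-removal rule applied at occasion 2.
- name: no_intervention
  fraction: 0.0
  rule: none
- name: deg10_below35
  fraction: 0.10
  rule: remove_below
  threshold: 35.0
- name: deg10_above45
  fraction: 0.10
  rule: remove_above
  threshold: 45.0
- name: deg20_below35
  fraction: 0.20
  rule: remove_below
  threshold: 35.0
- name: deg20_above45
  fraction: 0.20
  rule: remove_above
  threshold: 45.0
- name: defor5
  fraction: 0.05
  rule: remove_all
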