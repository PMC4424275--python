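# Sample sizes: 375 plots assessed at each occasion for every design.
- design: temporary
  n_t1_only: 375
  n_permanent: 0
  n_t2_only: 375
- design: cfi
  n_t1_only: 0
  n_permanent: 375
  n_t2_only: 0
- design: spr
  n_t1_only: 125
  n_permanent: 250
  n_t2_only: 125
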