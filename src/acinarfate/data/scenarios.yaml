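# Scenario catalogue: the simulation conditions of the study.
# bile: 0 = unstimulated, 1 = 200 uM TLC-S, 2 = 500 uM TLC-S
# antiox: inhibited = DMN (AntiOx clamped to 0), normal, added = NAC (clamped to 2)
steps: 40
scenarios:
  - {bile: 0, antiox: normal}
  - {bile: 1, antiox: normal}
  - {bile: 2, antiox: normal}
  - {bile: 0, antiox: inhibited}
  - {bile: 1, antiox: inhibited}
  - {bile: 2, antiox: inhibited}
  - {bile: 1, antiox: added}
  - {bile: 2, antiox: added}
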