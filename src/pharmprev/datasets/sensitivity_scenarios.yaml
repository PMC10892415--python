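# One-at-a-time sensitivity scenarios: literature extremes for each
# model parameter, varied one per run while all others stay at base.
scenarios:
  - name: adherence-50
    adherence_nad: 0.50
  - name: adherence-92
    adherence_nad: 0.92
  - name: insulin-users-6.0
    insulin_t2dm_fraction: 0.060
  - name: insulin-users-15.8
    insulin_t2dm_fraction: 0.158
  - name: concomitance-0.596
    w: 0.596
  - name: undiagnosed-9.8
    undiagnosed_fraction: 0.098
  - name: undiagnosed-50
    undiagnosed_fraction: 0.50
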