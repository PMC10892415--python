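# Base-case parameters of the prevalence estimation model.
adherence_nad: 0.60
adherence_insulin: 1.00
w: 0.608
insulin_t2dm_fraction: 0.075
undiagnosed_fraction:
  2018: 0.44
  2021: 0.357
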