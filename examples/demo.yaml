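# Demo: synthetic 4-area recording with a planted causal chain 1->2->3->4,
# reference SDAE widths (8, 3), conditional GC with permutation test.
synthetic:
  duration: 30.0
apply_bandpass: false
select_widths: false
n: 8
m: 3
train:
  epochs: 80
  seed: 0
n_perm: 199
alpha: 0.01
condition: awake
outdir: demo_run
seed: 7
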