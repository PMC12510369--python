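# Demo run: fully synthetic enrichment scenario, desk scale.
simulate:
  scenario: enrichment
  n_orfs: 300
  lysis_rate: 0.02
outdir: demo_run
seed: 7
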