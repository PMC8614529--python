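# Small demonstration scenario for `ssgblup simulate --config examples/demo.yaml`
# (fiber-diameter-like trait; runs in a few seconds)
trait: FD
n_founders: 150
n_generations: 3
n_snps: 400
n_qtl: 80
n_years: 8
prop_genotyped: 0.2
mean_records: 2.0
seed: 2021
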