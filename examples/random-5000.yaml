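# Full sample-size x order x family grid on a random 5,000 stems/ha stand.
# Run:  pcqm simulate --config examples/random-5000.yaml --out-dir results
version: 1
scenarios:
  - id: random-5000
    pattern: {kind: random, n: 5000, width: 100, height: 100}
    sample_sizes: [10, 15, 20, 25, 30, 50, 100]
    orders: [1, 2, 3]
    estimators: [corrected, published]
    replicates: 1000
    boundary_fraction: 0.10
    seed: 1
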