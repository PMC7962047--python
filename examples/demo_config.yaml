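# Three-sample demo run: an expansion family with a de novo interruption.
# Run with:  repeatlens run --config examples/demo_config.yaml
out_dir: out/demo
seed: 42
expansion_threshold: 50
simulate:
  reads_per_sample: 2000
prep:
  min_passes: 3
  min_read_quality: 0.99
  analysis_cap: 10000
samples:
  - sample_id: E1
    barcode_name: BC1018_Forward
    alleles:
      - pattern: "(CTG)5"
        fraction: 0.06
        mosaicism: {family: point, location: 5}
      - pattern: "(CTG)n"
        n: 440
        fraction: 0.94
        mosaicism: {family: lognormal, mode: 447, sigma: 0.25}
  - sample_id: E2.1
    barcode_name: BC1019_Forward
    alleles:
      - pattern: "(CTG)13"
        fraction: 0.06
        mosaicism: {family: point, location: 13}
      - pattern: "(CTG)n(CCGCTG)(CTG)7(CCGCTG)(CTG)11"
        n: 350
        fraction: 0.94
        mosaicism: {family: lognormal, mode: 383, sigma: 0.20}
  - sample_id: E3
    barcode_name: BC1020_Forward
    alleles:
      - pattern: "(CTG)31"
        fraction: 0.06
        mosaicism: {family: point, location: 31}
      - pattern: "(CTG)n(CCGCTG)2(CTG)3(CCGCTG)2(CTG)5(CCGCTG)(CTG)7(CCGCTG)(CTG)11"
        n: 140
        fraction: 0.94
        mosaicism:
          family: mixture
          components:
            - {mode: 173, sigma: 0.05, weight: 0.5}
            - {mode: 215, sigma: 0.05, weight: 0.5}
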