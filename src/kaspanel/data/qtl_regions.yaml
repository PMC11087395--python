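# Default QTL-window registry: published genomic regions associated with
# percent germination and mesocotyl elongation under deep-sown direct-seeded
# rice cultivation (rice MSUv7 / IRGSP coordinates, Mb).
regions:
  - id: qSD3.1
    chromosome: "3"
    start_mb: 16.67
    end_mb: 24.65
    trait: germination_mesocotyl
  - id: qSD3.2
    chromosome: "3"
    start_mb: 32.31
    end_mb: 35.46
    trait: germination_mesocotyl
  - id: qSD4.1
    chromosome: "4"
    start_mb: 15.91
    end_mb: 21.50
    trait: germination_mesocotyl
  - id: qSD7.1
    chromosome: "7"
    start_mb: 10.18
    end_mb: 15.01
    trait: germination_mesocotyl
  - id: qSD7.2
    chromosome: "7"
    start_mb: 20.93
    end_mb: 24.26
    trait: germination_mesocotyl
  - id: qSD8.1
    chromosome: "8"
    start_mb: 19.86
    end_mb: 20.01
    trait: germination_mesocotyl
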