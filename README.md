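# kaspanel

Design, quality control and core-panel selection of trait-linked KASP
(Kompetitive Allele-Specific PCR) markers for deep-sown direct-seeded rice
breeding.

## The problem

Direct-seeded rice sown 10 cm deep only emerges if the seedling elongates
its mesocotyl fast enough to reach the surface; elite cultivars mostly do
not. Breeding programs introgress favourable alleles from deep-sowing
tolerant donors (Aus344, N22, Kula Karuppan, NCS237, IRGC 128442) into elite
recipients (PR121, PR126, PR128, PR129, PB1509, MTU1010) and need cheap,
reliable single-SNP assays to track those alleles through backcross and
selfing generations. `kaspanel` implements the downstream half of building
such an assay panel:

1. **Variant screening** — merge parental variant tables, apply the
   MAF > 2% / call-rate ≥ 80% retention rule, restrict to the six published
   QTL windows for germination and mesocotyl elongation (qSD3.1, qSD3.2,
   qSD4.1, qSD7.1, qSD7.2, qSD8.1), and keep donor-specific SNPs — sites
   where a donor and a recipient are opposite homozygotes. The recipients a
   marker separates from the donor form its **utility set**.
2. **Assay design** — extract 100-bp flanks, emit bracketed `[ref/alt]`
   design input, construct the two allele-specific primers (3′ base on the
   SNP, FAM/HEX tails) plus a common reverse primer under length, Tm and
   amplicon constraints, and reject assays whose 3′-anchored primer core
   matches the genome more than once.
3. **Genotype calling** — angle-based clustering of two-channel endpoint
   fluorescence into donor-hom / het / recipient-hom with a no-call guard
   band.
4. **Marker QC** — per marker and population: allele-class counts and
   frequencies, false-positive rate `FPR = #(truth-recipient lines called
   non-recipient) / #(truth-recipient lines)`, false-negative rate
   `FNR = #(truth donor-allele carriers called without it) / #(carriers)`,
   Kruskal–Wallis allelic-effect tests with `*`/`**`/`***` tiers, single-
   marker regression R², and the CRD ANOVA `Y_ij = μ + α_i + e_ij` with
   `CV% = 100·√MSE / mean`.
5. **Panel selection** — spacing summaries in kb and cM (1 cM ≈ 244 kb),
   utility histograms, criteria-based core-panel nomination with an audit
   trail, and favourable-allele frequency matrices for heat maps.

Because the underlying study material is not deposited, the package ships a
first-class **synthetic-study generator**: reference chromosomes, parental
variant profiles with planted donor-specific candidates, seven F₃:F₄
(256 progeny) and eight BC₃F₂:₃ (713 progeny) populations with pedigree
truth, tray-level germination and seedling-length phenotypes, and
controlled assay-error injection — so every statistic above can be
validated against known ground truth.

A curated transcription of the published 54-marker validation table and the
published 12-assay core panel are bundled as package data
(`kaspanel.io.load_table3`, `kaspanel.io.load_core_panel`).

## Worked example

```python
from kaspanel import panel, pipeline
from kaspanel.io import load_table3
from kaspanel import simulate as sim

# bundled 54-marker panel: how many backgrounds is each assay usable in?
table = load_table3()
print(panel.utility_histogram(table["utility_backgrounds"]))
# {5: 13, 4: 15, 3: 5, 2: 8, 1: 13}
#  -> 13 assays work in five recipient backgrounds, 13 in only one.

print(round(panel.cm_from_kb(505), 3))
# 2.07   (505 kb at the 244 kb/cM rice heuristic)

# synthetic study at 2% genome scale, full pipeline
cfg, regions = sim.desk_scale_config(seed=1, scale=0.02)
res = pipeline.run_all(cfg, regions)
print(res["funnel"])
# {'planted': 54, 'screened': 54, 'designed': 35, 'accepted': 35,
#  'polymorphic': 32, 'selected': 26}
```

The funnel mirrors a real campaign: 54 donor-specific candidates are
planted and screened, a fraction fail primer design constraints (Tm window
unreachable on their flanks), the accepted assays are genotyped on ~970
simulated progeny with injected error, and the QC thresholds admit a core
subset.

The same pipeline is available from a shell:

```
kaspanel simulate --seed 1 --out study/          # synthetic FASTA/VCF/CSVs
kaspanel run-all  --seed 1 --out results/        # screen→design→call→qc→select
kaspanel fixture-report                          # bundled-panel summaries
```

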