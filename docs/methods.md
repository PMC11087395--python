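# Methods

This note records the models, conventions and numerical choices behind
`kaspanel`, in the order data flows through the package.

## Coordinates, codes and bundled data

All genomic coordinates are 1-based inclusive (VCF convention); window
bounds given in Mb convert as Mb × 10⁶ with inclusive endpoints. Genotypes
are coded 0 (homozygous reference / recipient), 1 (heterozygous),
2 (homozygous alternate / donor) and −1 (missing); in progeny matrices the
code is the donor-allele dosage. Marker display ids follow the `K_<position>`
scheme; internal keys are (chromosome, position) pairs because positions
alone are not unique across chromosomes.

Two reference tables ship with the package. `kasp_panel54.csv` is a curated
transcription of the published quality-control table for the 54 polymorphic
deep-sowing KASP assays, protected by a SHA-256 checksum. Its two population
blocks are labelled `population_class_A`/`B` exactly as printed, because the
printed NILs/RILs column labels contradict the accompanying prose; internal
evidence (maximum n_tested 713 vs 256, and the FPR/FNR ranges) identifies
class A with the BC₃F₂:₃ material and class B with the F₃:F₄ material. Rows
whose printed percentages, sample sizes or decimal glyphs are internally
inconsistent are preserved as printed and flagged in a `provenance_flags`
column; consumers that recompute frequencies skip flagged entries. Three
chromosome-7 markers (K_10023203, K_10068231, K_10131516) lie slightly below
the printed 10.18 Mb lower bound of qSD7.1; region assignment reports them
as unassigned rather than silently widening the window. The published
12-assay core panel is shipped as a pinned id list because the published
selection prints no numeric thresholds; the panel-selection code instead
exposes criteria-as-config (`PanelSelectionCriteria`).

## Synthetic study generator

The generator emulates the study design, not any particular dataset. All
randomness derives from one master seed through named substreams
(reference / parents / cross / phenotype / error), so a fixed configuration
reproduces byte-identical artifacts.

**Reference and parents.** Chromosomes 3, 4, 7 and 8 are simulated i.i.d.
at GC 0.44 (read-level GC in such material runs 43–48%). Background SNPs
(default 50 per Mb — far sparser than real resequencing, but enough to give
parent-level analyses realistic two-group structure) are planted genome-wide;
half of them differentiate the donor group from the recipient group with
occasional crossovers, the rest segregate randomly. Donor-specific candidate
SNPs (default 9 per QTL window, 54 in all) are planted inside the windows:
the owning donor is alternate-homozygous, other donors reference, and each
recipient is reference (informative; member of the utility set) or
alternate (blind) according to a utility-set size drawn from the published
histogram 13/15/5/8/13 for sizes 5/4/3/2/1. One recipient background (the
MTU1010-like sixth) is withheld from utility planting, mirroring the five
backgrounds actually screened.

**Crosses.** Loci are unlinked; linkage enters the package only through the
fixed 244 kb/cM conversion used in spacing reports. F₃:F₄ progeny are
genotyped after three selfing meioses from the F₁, so the expected
heterozygote fraction at a segregating locus is (1/2)³ = 1/8 and each
homozygote has probability 7/16. BC₃F₂:₃ progeny are genotyped at BC₃F₂:
foreground selection is modelled as certain, the BC₃F₁ is heterozygous at
every segregating target locus, and one selfing meiosis gives 1:2:1 — hence
the ¾ donor-allele carrier frequency characteristic of foreground-selected
backcross material. Background (unselected) loci survive the three
backcrosses heterozygous with probability (1/2)³ before the self. Both
meiosis counts are configurable; single-seed descent is assumed throughout
(the founding scheme of the real families is not recorded anywhere usable).

**Phenotypes.** Deep-sowing emergence behaves like a major-effect trait, so
each population's phenotype is driven by a single causal locus — the first
planted causal candidate (genome order) that segregates in that cross. This
choice is forced by arithmetic: within-population class separations as
large as the published ones (≈22% vs ≈69% germination against parental
extremes of ≈14% and ≈83%) cannot coexist with six independently
segregating additive windows, which would inflate every marginal class mean.
Germination is simulated as emerged-seed counts out of 6 per tray × 3
replicates (CRD; both the replicate count and seeds per tray are
configurable, since some published percentages imply a 12-seed grid), with
per-seed emergence probability logistic in the driver dosage: baseline
p = 0.22 at 10 cm and 0.45 at 4 cm, homozygous effect +2.02 logit at 10 cm
(heterozygotes additive at half). Mesocotyl, root and shoot lengths are
Gaussian around genotype-class means (10 cm mesocotyl baseline 1.0 cm,
homozygous effect +3.5 cm, σ = 0.3 cm), truncated at zero with a warning
counter. These defaults put the 10 cm donor-homozygous vs
recipient-homozygous class means near 68%/22% germination and 4.5/1.0 cm
mesocotyl — mid-range of the published validation spans (54.65–83.3% vs
14.26–31.04%; 3.19–5.84 cm vs 0.5–1.6 cm) — and are stable across seeds.

**Assay error.** Per line and marker, mutually exclusive events: a
recipient-homozygous truth is mis-called (het or donor-hom, equally likely)
with the false-positive rate; a carrier is mis-called recipient-homozygous
with the false-negative rate; either class is set missing with the missing
rate (defaults 0.10 / 0.04 / 0.02, inside the published per-population
ranges). Every flip is logged cell-by-cell, which is what makes the QC
recovery tests exact.

**What the generator does not emulate.** No recombination maps, no
epistasis, no genotype × environment interaction beyond the depth term, no
shared ancestry beyond the two-group background structure, and no
sequencing-level artifacts (the variant-calling stage upstream of the
package is out of scope). Passing tests therefore demonstrate the
correctness of the statistics and the pipeline plumbing under the stated
segregation model — not robustness to linkage drag, population structure or
real fluorescence chemistry.

## Screening and design conventions

"Retaining at least 80% of the data" is read as a per-site call rate across
samples (the filter operates on variants, not samples); MAF must strictly
exceed the 2% threshold, computed diploid over called samples.
Donor-specificity is conservative: only opposite homozygotes count, and a
heterozygous or missing parental call excludes that recipient from the
utility set rather than being phased or imputed — these are inbred parents,
so a het call is treated as unreliable.

Primer design fixes the allele-specific 3′ end on the SNP and grows the
primer 5′-ward (18–28 nt) until the melting temperature enters the 57–63 °C
window, preferring minimal |Tm − 60| then shorter length; the two
allele-specific primers are forced to a common core length so they differ
only at the 3′ base and their fluorophore tails (the widely published
FAM/HEX tail oligos by default — the tails are configuration, not
constants). The common reverse primer is chosen the same way subject to a
50–120 bp amplicon. Melting temperatures come from Biopython:
Wallace 2(A+T)+4(G+C) or the unified nearest-neighbor stack at default
oligo/salt concentrations; tails are excluded. Multi-locus rejection
replaces a BLAST alignment with an exact search (both strands, overlapping)
of the 3′-anchored 16-nt primer core — the rejection semantics are
preserved while the result is exactly reproducible; a mismatch tolerance is
available in configuration. On random desk-scale genomes roughly a third of
candidates fail the Tm constraints; this is the honest consequence of a
fixed 3′ anchor and is reported in the pipeline funnel rather than hidden.

## Calling

Fluorescence calls are one-dimensional k-means on the signal angle
θ = atan2(donor-channel, recipient-channel), seeded at 0°/45°/90°, with a
minimum-intensity floor and a ±10° no-call guard band around cluster
boundaries; if fewer than three clusters are occupied the heterozygote
calls are demoted to missing. Angle space makes calls invariant to uniform
channel scaling and matches the visual geometry of KASP cluster plots;
two-dimensional mixture models were deliberately avoided as
non-deterministic and unnecessary for synthetic validation. The synthetic
renderer maps classes to the canonical angles with Gaussian angular/radial
noise; at zero noise calling recovers truth exactly, and at 2% noise
concordance sits in the ≥99% repeatability regime reported for the
platform.

## QC statistics

Positive/negative allele classes are homozygote-only (the published
frequency pairs never sum to 100%, implying heterozygotes and missing calls
were excluded); class frequencies are percentages of all tested lines, to
one decimal. FPR and FNR require a truth channel — simulation truth by
default, or a designated reference-assay matrix; missing calls count as
discordant in both numerators by default (strict), toggleable. Markers are
summarized within the populations where they are informative, matching the
varying per-marker sample sizes of the published table. The Kruskal–Wallis
test runs on the two homozygote classes (tie-corrected, chi-square
approximation with k−1 df; the heterozygote class can be added as a third
group — the published computation's grouping is not stated, so neither mode
is asserted as "the" published one). The chi-square p agrees with the exact
permutation p to within 0.02 wherever significance tiers are decided
(p < 0.1; verified by enumerating the exact tie-free null for groups ≤ 10)
but deviates by up to ~0.05 deep in the null — a documented property of the
approximation, not an implementation defect. Single-marker analysis is OLS
of phenotype on 0/1/2 dosage with the F(1, n−2) p-value; the CRD ANOVA
reports CV% = 100·√MSE/mean and flags an infinite F when MSE is exactly
zero. No multiple-testing adjustment is applied across markers, matching
the source analysis; this is a known limitation.

## Panel summaries and selection

Marker spacing is the mean of adjacent (not all-pairs) sorted-position
differences, converted at 244 kb/cM. Selection is monotone in every
threshold: markers passing max-FPR/max-FNR/min-utility/significance gates
are ranked by utility (desc), FPR, FNR, then Kruskal–Wallis p, with marker
id as the final deterministic tie-break; an audit trail records every
pass/fail. Genetic distance between parents is the simple genotype-mismatch
proportion over shared non-missing sites (the published distance is
unnamed; an allele-sharing variant would differ only by a factor at these
inbred parents). UPGMA uses arithmetic-mean linkage with lexicographic
tie-breaks and emits ultrametric Newick (heights are half the merge
distance, 12 significant digits — enough for the ultrametry checks). PCA is
the SVD of the column-centered dosage matrix with per-site mean imputation
of missing calls and zero-variance sites dropped. Variant functional
context uses the precedence CDS > UTR > intron > intergenic across
overlapping models; coding effects translate reference and alternate codons
under the standard code, strand-aware, with stop gain/loss mapped to
"other". SIFT-style deleteriousness scoring is out of scope; a pass-through
column carries externally supplied scores.

## Problem sizes

Tests and the acceptance script run the study at reduced genome scale
(typically 2% of the real chromosome lengths, with the QTL registry scaled
in proportion) and full population sizes (256 + 713 progeny); stochastic
recovery checks use 10 000 progeny at a single locus, where binomial
3σ bounds are tight. These sizes were chosen so the whole validation cycle
completes in well under a minute while every statistical claim remains
testable at its stated tolerance.
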