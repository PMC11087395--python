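"""Synthetic breeding-study generator.

Emulates the material behind a deep-sowing KASP validation study: a rice-like
reference for chromosomes 3/4/7/8, five donor and six recipient parental
variant profiles with donor-specific SNPs planted inside the QTL windows,
seven F3:F4 (256 progeny) and eight BC3F2:3 (713 progeny) biparental
populations with pedigree truth, depth-structured phenotypes (germination
from 6-seed x 3-replicate trays, mesocotyl/root/shoot lengths) and noisy
assay calls with controlled false-positive / false-negative / missing rates.

All randomness flows from one master seed through named substreams
(reference / parents / cross / phenotype / error), so identical
configuration gives byte-identical outputs.

Segregation model
-----------------
Loci are unlinked. One designated causal locus per QTL window carries the
window's phenotypic effect; the remaining planted candidates in the window
segregate but are phenotypically neutral (no recombination-map realism).
F3:F4 progeny are genotyped after three selfing meioses from the F1
(heterozygote fraction 1/8); BC3F2:3 progeny are genotyped at BC3F2, one
selfing meiosis after a foreground-selected (certainly heterozygous) BC3F1,
so the donor-allele carrier frequency at target loci is 3/4.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import HET, HOM_ALT, HOM_REF, MISSING, QTLRegion, ValidationError, VariantTable
from .io import load_qtl_registry

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")

DONORS = ["Aus344", "N22", "KulaKaruppan", "NCS237", "IRGC128442"]
RECIPIENTS = ["PR121", "PR126", "PR128", "PR129", "PB1509", "MTU1010"]

# Empirical distribution of background-utility cardinalities in the published
# 54-assay panel: 13/15/5/8/13 markers informative against 5/4/3/2/1 of the
# five recipient backgrounds screened there.
UTILITY_SIZE_WEIGHTS = {5: 13, 4: 15, 3: 5, 2: 8, 1: 13}


@dataclass(frozen=True)
class RegionEffect:
    """Phenotypic effect of the donor allele at one QTL window.

    Germination effects are additive on the logit of per-seed emergence
    probability (value = homozygous-donor effect; heterozygotes get half).
    Length effects are additive in cm on the genotype-class mean.
    """

    germination_logit_10cm: float = 2.02
    germination_logit_4cm: float = 0.30
    mesocotyl_cm_10cm: float = 3.5
    mesocotyl_cm_4cm: float = 0.5
    root_cm_10cm: float = 0.8
    root_cm_4cm: float = 0.3


@dataclass(frozen=True)
class PopulationSpec:
    population_id: str
    cross_type: str  # "F3:F4" | "BC3F2:3"
    donor: str
    recipient: str
    n_progeny: int

    def __post_init__(self):
        if self.cross_type not in ("F3:F4", "BC3F2:3"):
            raise ValidationError(f"unknown cross type {self.cross_type!r}")
        if self.n_progeny <= 0:
            raise ValidationError("n_progeny must be positive")


def default_population_specs() -> list[PopulationSpec]:
    """The study's fifteen validation populations: seven F3:F4 families
    totalling 256 progeny and eight BC3F2:3 families totalling 713."""
    f34 = [
        ("PR121", "N22"), ("PR126", "N22"), ("PR128", "N22"), ("PB1509", "N22"),
        ("PR121", "Aus344"), ("PR129", "Aus344"), ("PR128", "IRGC128442"),
    ]
    bc = [
        ("N22", "PR121"), ("N22", "PR126"), ("N22", "PR128"), ("N22", "PB1509"),
        ("Aus344", "PR121"), ("Aus344", "PR129"),
        ("IRGC128442", "PR126"), ("IRGC128442", "PR128"),
    ]
    f34_sizes = [37, 37, 37, 37, 36, 36, 36]           # 256
    bc_sizes = [90, 89, 89, 89, 89, 89, 89, 89]        # 713
    specs = [
        PopulationSpec(f"{rec}x{don}_F3F4", "F3:F4", don, rec, n)
        for (rec, don), n in zip(f34, f34_sizes)
    ]
    specs += [
        PopulationSpec(f"{don}-4x{rec}_BC3F23", "BC3F2:3", don, rec, n)
        for (don, rec), n in zip(bc, bc_sizes)
    ]
    return specs


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the study design."""

    seed: int = 0
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {
            # rice MSUv7-like pseudomolecule sizes for the four relevant chromosomes
            "3": 36_400_000,
            "4": 35_500_000,
            "7": 29_700_000,
            "8": 28_400_000,
        }
    )
    gc_content: float = 0.44
    snp_density_per_mb: float = 50.0      # shared background SNPs
    candidates_per_region: int = 9        # 6 windows -> 54 donor-specific candidates
    donors: list[str] = field(default_factory=lambda: list(DONORS))
    recipients: list[str] = field(default_factory=lambda: list(RECIPIENTS))
    qtl_effects: dict[str, RegionEffect] = field(default_factory=dict)
    # per-call error model: mutually exclusive flip/missing events per line
    false_positive_call_rate: float = 0.10
    false_negative_call_rate: float = 0.04
    missing_rate: float = 0.02
    population_specs: list[PopulationSpec] = field(default_factory=default_population_specs)
    replicates: int = 3                   # germination trays per progeny per depth
    seeds_per_replicate: int = 6
    f3f4_selfing_meioses: int = 3
    bc_backcrosses: int = 3
    bc_selfing_meioses: int = 1
    # phenotype baselines (recipient-homozygous class)
    germination_p_4cm: float = 0.45
    germination_p_10cm: float = 0.22
    mesocotyl_cm_4cm: float = 2.0
    mesocotyl_cm_10cm: float = 1.0
    mesocotyl_sd_cm: float = 0.30
    root_cm_4cm: float = 4.5
    root_cm_10cm: float = 3.3
    root_sd_cm: float = 1.0
    shoot_cm_4cm: float = 19.0
    shoot_cm_10cm: float = 19.0
    shoot_sd_cm: float = 3.0

    def __post_init__(self):
        for name in ("false_positive_call_rate", "false_negative_call_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.false_positive_call_rate + self.missing_rate > 1.0:
            raise ValidationError("false_positive_call_rate + missing_rate exceeds 1")
        if self.false_negative_call_rate + self.missing_rate > 1.0:
            raise ValidationError("false_negative_call_rate + missing_rate exceeds 1")

    def effect_for(self, region_id: str) -> RegionEffect:
        return self.qtl_effects.get(region_id, RegionEffect())

    def substream(self, name: str) -> np.random.Generator:
        """Named child RNG derived from the master seed."""
        offsets = {"reference": 0, "parents": 1, "cross": 2, "phenotype": 3, "error": 4}
        ss = np.random.SeedSequence(self.seed, spawn_key=(offsets[name],))
        return np.random.default_rng(ss)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population_specs"] = [dataclasses.asdict(p) for p in self.population_specs]
        d["qtl_effects"] = {k: dataclasses.asdict(v) for k, v in self.qtl_effects.items()}
        return d


def desk_scale_config(seed: int = 0, scale: float = 0.05) -> tuple[SimulationConfig, list[QTLRegion]]:
    """A proportionally shrunk genome plus matching registry for fast runs.

    Window coordinates and chromosome lengths are multiplied by ``scale``;
    population structure, error rates and effects are untouched.
    """
    full = load_qtl_registry()
    regions = [
        QTLRegion(r.id, r.chromosome, int(r.start_bp * scale), int(r.end_bp * scale), r.trait)
        for r in full
    ]
    cfg = SimulationConfig(seed=seed)
    cfg.chromosome_lengths = {c: int(n * scale) for c, n in cfg.chromosome_lengths.items()}
    return cfg, regions


@dataclass
class ProgenyRecord:
    """One progeny line with pedigree truth and (optionally) noisy calls."""

    progeny_id: str
    population_id: str
    true_genotype: dict[str, int]
    called_genotype: dict[str, int] | None = None
    phenotypes: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# reference and parents


def generate_reference(config: SimulationConfig) -> dict[str, str]:
    """Random chromosome sequences at the configured GC fraction."""
    rng = config.substream("reference")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for chrom, length in config.chromosome_lengths.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom} has non-positive length {length}")
        idx = rng.choice(4, size=length, p=p)
        out[chrom] = BASES[idx].tobytes().decode("ascii")
    return out


def _draw_utility_sizes(rng, n, recipients_screened):
    sizes = np.array(sorted(UTILITY_SIZE_WEIGHTS))
    w = np.array([UTILITY_SIZE_WEIGHTS[s] for s in sizes], dtype=float)
    sizes = np.minimum(sizes, len(recipients_screened))
    return rng.choice(sizes, size=n, p=w / w.sum())


def generate_parents(
    config: SimulationConfig,
    reference: dict[str, str],
    regions: list[QTLRegion] | None = None,
) -> tuple[VariantTable, pd.DataFrame]:
    """Parental variant profiles with planted donor-specific candidates.

    Returns the merged parental :class:`VariantTable` and a ``planted``
    truth frame (chrom, pos, ref, alt, donor, utility_set, region_id,
    causal) describing every donor-specific candidate by construction.
    Background SNPs differentiate the donor and recipient groups so that
    parent-level diversity analyses see two clusters.
    """
    if regions is None:
        regions = load_qtl_registry()
    rng = config.substream("parents")
    donors, recipients = config.donors, config.recipients
    samples = donors + recipients
    # the five recipients entering polymorphism screens (one recipient, the
    # MTU1010-like background, is withheld from utility planting by default)
    screened = recipients[:5]

    site_rows, geno_rows, planted_rows = [], [], []

    # background SNPs, genome-wide
    for chrom, length in config.chromosome_lengths.items():
        n_bg = int(round(config.snp_density_per_mb * length / 1e6))
        if n_bg == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n_bg, length), replace=False))
        for p in pos:
            ref = reference[chrom][p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            if rng.random() < 0.5:
                # group-differentiating site: donors carry the alternate allele
                g = [HOM_ALT] * len(donors) + [HOM_REF] * len(recipients)
                # occasional crossover of one sample keeps groups imperfect
                if rng.random() < 0.2:
                    g[rng.integers(len(samples))] = HOM_REF if rng.random() < 0.5 else HOM_ALT
            else:
                g = list(rng.choice([HOM_REF, HOM_ALT], size=len(samples), p=[0.7, 0.3]))
            site_rows.append((chrom, int(p), ref, alt))
            geno_rows.append(g)

    # donor-specific candidates inside each QTL window
    for region in regions:
        if region.chromosome not in reference:
            raise ValidationError(f"region {region.id} on unknown chromosome {region.chromosome}")
        chrom_len = config.chromosome_lengths[region.chromosome]
        lo, hi = region.start_bp, min(region.end_bp, chrom_len)
        if hi <= lo:
            raise ValidationError(f"region {region.id} lies outside the generated chromosome")
        n_cand = config.candidates_per_region
        if n_cand == 0:
            log.warning("region %s: zero candidates requested, none planted", region.id)
            continue
        pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_cand, replace=False))
        sizes = _draw_utility_sizes(rng, n_cand, screened)
        causal_idx = int(np.argmin(np.abs(pos - (lo + hi) / 2)))
        for k, (p, usize) in enumerate(zip(pos, sizes)):
            ref = reference[region.chromosome][p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            donor = donors[int(rng.integers(len(donors)))]
            utility = sorted(rng.choice(screened, size=int(usize), replace=False))
            g = []
            for s in donors:
                # strictly donor-specific: other donors carry the reference
                g.append(HOM_ALT if s == donor else HOM_REF)
            for s in recipients:
                if s in utility:
                    g.append(HOM_REF)
                else:
                    g.append(HOM_ALT)  # same allele as donor: uninformative background
            site_rows.append((region.chromosome, int(p), ref, alt))
            geno_rows.append(g)
            planted_rows.append(
                dict(
                    chrom=region.chromosome, pos=int(p), ref=ref, alt=alt,
                    donor=donor, utility_set=";".join(utility),
                    region_id=region.id, causal=(k == causal_idx),
                )
            )

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"])
    geno = pd.DataFrame(geno_rows, columns=samples, dtype=np.int8)
    table = VariantTable(sites, geno, donors=list(donors), recipients=list(recipients))
    table = table.sorted()
    # drop duplicated positions (background colliding with a candidate)
    dup = table.sites.duplicated(subset=["chrom", "pos"], keep="last")
    if dup.any():
        table = VariantTable(
            table.sites[~dup], table.genotypes[~dup.values],
            donors=table.donors, recipients=table.recipients,
        )
    planted = pd.DataFrame(planted_rows)
    if not planted.empty:
        planted = planted.sort_values(["chrom", "pos"]).reset_index(drop=True)
        planted["marker_id"] = "K_" + planted["pos"].astype(str)
    return table.validate(), planted


# ---------------------------------------------------------------------------
# crosses


def _selfing_probs(n_meioses: int) -> np.ndarray:
    """Genotype distribution after n selfing meioses from a heterozygote.

    Returns [P(recipient-hom), P(het), P(donor-hom)]; heterozygosity halves
    each meiosis.
    """
    h = 0.5 ** n_meioses
    return np.array([(1 - h) / 2, h, (1 - h) / 2])


def simulate_cross(
    spec: PopulationSpec,
    parents: VariantTable,
    seed_rng,
    loci: pd.DataFrame | None = None,
    target_regions: list[QTLRegion] | None = None,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Pedigree truth for one population at the given marker loci.

    Returns a progeny x marker int8 frame coded by donor-allele dosage
    (0 recipient-hom / 1 het / 2 donor-hom). Loci where donor and recipient
    do not differ as opposite homozygotes are non-segregating: all progeny
    are coded 0 and the locus is flagged in ``frame.attrs['non_segregating']``.
    """
    cfg = config or SimulationConfig()
    rng = seed_rng if isinstance(seed_rng, np.random.Generator) else np.random.default_rng(seed_rng)
    if loci is None:
        loci = parents.sites
    keys = parents.site_keys()
    idx = [keys.get_loc((c, p)) for c, p in zip(loci["chrom"], loci["pos"])]
    d_gt = parents.genotypes[spec.donor].to_numpy()[idx]
    r_gt = parents.genotypes[spec.recipient].to_numpy()[idx]

    segregating = ((d_gt == HOM_REF) & (r_gt == HOM_ALT)) | ((d_gt == HOM_ALT) & (r_gt == HOM_REF))
    marker_ids = ["K_" + str(p) for p in loci["pos"]]

    n = spec.n_progeny
    out = np.zeros((n, len(marker_ids)), dtype=np.int8)

    in_target = np.zeros(len(marker_ids), dtype=bool)
    if target_regions is None and spec.cross_type == "BC3F2:3":
        target_regions = load_qtl_registry()
    if target_regions:
        for j, (c, p) in enumerate(zip(loci["chrom"], loci["pos"])):
            in_target[j] = any(r.contains(c, p) for r in target_regions)

    if spec.cross_type == "F3:F4":
        probs = _selfing_probs(cfg.f3f4_selfing_meioses)
        for j in np.nonzero(segregating)[0]:
            out[:, j] = rng.choice(3, size=n, p=probs)
    else:  # BC3F2:3
        probs_target = _selfing_probs(cfg.bc_selfing_meioses)
        p_het_bc = 0.5 ** cfg.bc_backcrosses  # unselected het survival through backcrosses
        for j in np.nonzero(segregating)[0]:
            if in_target[j]:
                out[:, j] = rng.choice(3, size=n, p=probs_target)
            else:
                het_at_bc3 = rng.random(n) < p_het_bc
                draws = rng.choice(3, size=n, p=probs_target)
                out[:, j] = np.where(het_at_bc3, draws, 0)

    frame = pd.DataFrame(
        out,
        index=[f"{spec.population_id}_{i+1:04d}" for i in range(n)],
        columns=marker_ids,
    )
    frame.attrs["non_segregating"] = [m for m, s in zip(marker_ids, segregating) if not s]
    frame.attrs["population_id"] = spec.population_id
    return frame


def simulate_population_truth(
    config: SimulationConfig,
    parents: VariantTable,
    planted: pd.DataFrame,
    regions: list[QTLRegion] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Truth genotypes for every configured population at the planted loci."""
    rng = config.substream("cross")
    frames, pops = [], []
    loci = planted[["chrom", "pos"]]
    for spec in config.population_specs:
        f = simulate_cross(spec, parents, rng, loci=loci, target_regions=regions, config=config)
        frames.append(f)
        pops.extend([spec.population_id] * len(f))
    truth = pd.concat(frames, axis=0)
    populations = pd.Series(pops, index=truth.index, name="population_id")
    return truth, populations


# ---------------------------------------------------------------------------
# phenotypes


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def assign_population_drivers(config: SimulationConfig, planted: pd.DataFrame) -> dict[str, str | None]:
    """The causal locus driving each population's phenotype.

    Deep-sowing emergence behaves like a major-effect trait: each cross is
    dominated by one segregating QTL. The driver is the first causal locus
    (genome order) that segregates in the cross — its donor matches and its
    utility set contains the recipient. Populations with no segregating
    causal locus express baseline phenotypes only.
    """
    drivers: dict[str, str | None] = {}
    causal = planted[planted["causal"]] if not planted.empty else planted
    for spec in config.population_specs:
        driver = None
        for row in causal.itertuples(index=False):
            if row.donor == spec.donor and spec.recipient in row.utility_set.split(";"):
                driver = row.marker_id
                break
        drivers[spec.population_id] = driver
    return drivers


def germination_counts_to_percent(counts: np.ndarray, seeds_per_replicate: int) -> np.ndarray:
    """Percent germination from emerged-seed counts over replicates."""
    total = counts.sum(axis=-1)
    planted = seeds_per_replicate * counts.shape[-1]
    return 100.0 * total / planted


def simulate_phenotypes(
    truth: pd.DataFrame,
    planted: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
    populations: pd.Series | None = None,
) -> pd.DataFrame:
    """Depth-structured phenotypes driven by each population's causal locus.

    Germination is simulated as emerged-seed counts out of
    ``seeds_per_replicate`` across ``replicates`` trays per depth (CRD), with
    per-seed emergence probability logistic in the allele effect at the
    population's driver locus (see :func:`assign_population_drivers`).
    Without a population assignment the effects of all causal loci sum.
    Lengths are Gaussian around genotype-class means, truncated at zero.
    Replicate-level counts are retained in ``germ_rep`` columns.
    """
    rng = rng or config.substream("phenotype")
    causal = planted[planted["causal"]]
    n = len(truth)

    # per-progeny dosage (0 / .5 / 1) weighted by each effect field
    if populations is None:
        dosage = np.clip(truth[causal["marker_id"]].to_numpy(float) / 2.0, 0, 1)
        effects = [config.effect_for(rid) for rid in causal["region_id"]]

        def shift(field):
            w = np.array([getattr(e, field) for e in effects])
            return dosage @ w

    else:
        drivers = assign_population_drivers(config, planted)
        region_of = dict(zip(causal["marker_id"], causal["region_id"]))
        driver_dosage = np.zeros(n)
        driver_region = np.array([""] * n, dtype=object)
        pop_arr = populations.loc[truth.index]
        for pop, marker in drivers.items():
            if marker is None:
                continue
            mask = (pop_arr == pop).to_numpy()
            driver_dosage[mask] = np.clip(truth.loc[mask, marker].to_numpy(float) / 2.0, 0, 1)
            driver_region[mask] = region_of[marker]

        def shift(field):
            w = np.array(
                [getattr(config.effect_for(r), field) if r else 0.0 for r in driver_region]
            )
            return driver_dosage * w

    out = {}
    n_truncated = 0
    for depth in (4, 10):
        base_p = getattr(config, f"germination_p_{depth}cm")
        logit = np.log(base_p / (1 - base_p)) + shift(f"germination_logit_{depth}cm")
        p = _logistic(logit)
        counts = rng.binomial(
            config.seeds_per_replicate, p[:, None], size=(n, config.replicates)
        )
        out[f"germination_pct_{depth}cm"] = germination_counts_to_percent(
            counts, config.seeds_per_replicate
        )
        for r in range(config.replicates):
            out[f"germ_rep{r+1}_{depth}cm"] = counts[:, r]
        meso = (
            getattr(config, f"mesocotyl_cm_{depth}cm")
            + shift(f"mesocotyl_cm_{depth}cm")
            + rng.normal(0, config.mesocotyl_sd_cm, size=n)
        )
        root = (
            getattr(config, f"root_cm_{depth}cm")
            + shift(f"root_cm_{depth}cm")
            + rng.normal(0, config.root_sd_cm, size=n)
        )
        shoot = getattr(config, f"shoot_cm_{depth}cm") + rng.normal(0, config.shoot_sd_cm, size=n)
        n_truncated += int((meso < 0).sum() + (root < 0).sum() + (shoot < 0).sum())
        meso, root, shoot = np.maximum(meso, 0), np.maximum(root, 0), np.maximum(shoot, 0)
        out[f"mesocotyl_cm_{depth}cm"] = meso
        out[f"root_cm_{depth}cm"] = root
        out[f"total_cm_{depth}cm"] = meso + root + shoot
    if n_truncated:
        log.warning("simulate_phenotypes: truncated %d negative length draws at 0", n_truncated)
    pheno = pd.DataFrame(out, index=truth.index)
    pheno.attrs["n_truncated"] = n_truncated
    return pheno


# ---------------------------------------------------------------------------
# assay error


def inject_assay_error(
    truth: pd.DataFrame,
    false_positive_call_rate: float,
    false_negative_call_rate: float,
    missing_rate: float,
    rng,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy assay calls from pedigree truth.

    Per line and marker the flip/missing events are mutually exclusive: a
    recipient-homozygous truth is mis-called (het or donor-hom) with the
    false-positive rate; a donor-allele carrier is mis-called
    recipient-homozygous with the false-negative rate; either class goes
    missing with the missing rate. Returns (calls, event_log) where
    ``event_log`` marks every altered cell with its event type.
    """
    for nm, r in (
        ("false_positive_call_rate", false_positive_call_rate),
        ("false_negative_call_rate", false_negative_call_rate),
        ("missing_rate", missing_rate),
    ):
        if not 0 <= r <= 1:
            raise ValidationError(f"{nm} out of [0,1]: {r}")
    if false_positive_call_rate + missing_rate > 1 or false_negative_call_rate + missing_rate > 1:
        raise ValidationError("per-class error rates sum above 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = truth.to_numpy()
    u = rng.random(t.shape)
    calls = t.copy()
    event = np.full(t.shape, "", dtype=object)

    is_recip = t == HOM_REF
    is_carrier = (t == HET) | (t == HOM_ALT)

    fp = is_recip & (u < false_positive_call_rate)
    flip_to = np.where(rng.random(t.shape) < 0.5, HET, HOM_ALT)
    calls[fp] = flip_to[fp]
    event[fp] = "false_positive"

    fn = is_carrier & (u < false_negative_call_rate)
    calls[fn] = HOM_REF
    event[fn] = "false_negative"

    miss = (
        (is_recip & (u >= false_positive_call_rate) & (u < false_positive_call_rate + missing_rate))
        | (is_carrier & (u >= false_negative_call_rate) & (u < false_negative_call_rate + missing_rate))
    )
    calls[miss] = MISSING
    event[miss] = "missing"

    calls_df = pd.DataFrame(calls, index=truth.index, columns=truth.columns).astype(np.int8)
    log_df = pd.DataFrame(event, index=truth.index, columns=truth.columns)
    return calls_df, log_df


# ---------------------------------------------------------------------------
# dataset driver


def generate_dataset(config: SimulationConfig, regions: list[QTLRegion] | None = None) -> dict:
    """Run the full generator: reference, parents, truth, phenotypes, calls."""
    if regions is None:
        regions = load_qtl_registry()
    reference = generate_reference(config)
    parents, planted = generate_parents(config, reference, regions)
    truth, populations = simulate_population_truth(config, parents, planted, regions)
    phenotypes = simulate_phenotypes(truth, planted, config, populations=populations)
    drivers = assign_population_drivers(config, planted)
    calls, events = inject_assay_error(
        truth,
        config.false_positive_call_rate,
        config.false_negative_call_rate,
        config.missing_rate,
        config.substream("error"),
    )
    return dict(
        reference=reference,
        parents=parents,
        planted=planted,
        truth=truth,
        populations=populations,
        phenotypes=phenotypes,
        calls=calls,
        error_events=events,
        drivers=drivers,
        regions=regions,
        config=config,
    )


def write_dataset(dataset: dict, outdir) -> None:
    """Emit FASTA / VCF / CSV artifacts plus a JSON metadata sidecar."""
    from pathlib import Path

    from .io import write_fasta, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: SimulationConfig = dataset["config"]
    write_fasta(dataset["reference"], outdir / "reference.fasta")
    write_vcf(dataset["parents"], outdir / "parents.vcf", contig_lengths=cfg.chromosome_lengths)
    dataset["planted"].to_csv(outdir / "planted_candidates.csv", index=False)
    dataset["truth"].to_csv(outdir / "genotype_truth.csv")
    dataset["calls"].to_csv(outdir / "genotype_calls.csv")
    dataset["phenotypes"].to_csv(outdir / "phenotypes.csv")
    dataset["populations"].to_csv(outdir / "populations.csv")
    meta = dict(config=cfg.to_dict(), seed=cfg.seed)
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
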