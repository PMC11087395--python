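"""Candidate-SNP triage: merge, quality filters, QTL-window restriction and
donor-specificity screening.

The quality filter keeps sites whose minor allele frequency strictly exceeds
``maf_min`` (default 2%) and whose per-site call rate is at least
``call_rate_min`` (default 80%), reproducing the resequencing pipeline's
variant-level retention rule. Donor specificity is conservative: a site
counts only where the donor and a recipient are opposite homozygotes —
heterozygous or missing parental calls never contribute to a utility set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CandidateSNP,
    QTLRegion,
    ValidationError,
    VariantTable,
)

log = logging.getLogger(__name__)


def merge_variant_tables(tables: list[VariantTable]) -> VariantTable:
    """Union of sites across tables; samples absent at a site become missing.

    Conflicting ref/alt alleles at a shared position are an error (same
    reference build is a precondition).
    """
    if not tables:
        raise ValidationError("no tables to merge")
    all_samples: list[str] = []
    for t in tables:
        for s in t.samples:
            if s in all_samples:
                raise ValidationError(f"sample id collision on merge: {s}")
            all_samples.append(s)

    alleles: dict[tuple, tuple] = {}
    for t in tables:
        for site in t.sites.itertuples(index=False):
            key = (site.chrom, site.pos)
            val = (site.ref, site.alt)
            if key in alleles and alleles[key] != val:
                raise ValidationError(
                    f"conflicting alleles at {key[0]}:{key[1]}: {alleles[key]} vs {val}"
                )
            alleles[key] = val

    keys = sorted(alleles, key=lambda k: (str(k[0]), k[1]))
    sites = pd.DataFrame(
        [(c, p, alleles[(c, p)][0], alleles[(c, p)][1]) for c, p in keys],
        columns=["chrom", "pos", "ref", "alt"],
    )
    gmat = pd.DataFrame(MISSING, index=range(len(keys)), columns=all_samples, dtype=np.int8)
    row_of = {k: i for i, k in enumerate(keys)}
    for t in tables:
        rows = [row_of[(c, p)] for c, p in zip(t.sites["chrom"], t.sites["pos"])]
        gmat.iloc[rows, [gmat.columns.get_loc(s) for s in t.samples]] = t.genotypes.to_numpy()
    donors = [s for t in tables for s in t.donors]
    recipients = [s for t in tables for s in t.recipients]
    return VariantTable(sites, gmat, donors=donors, recipients=recipients).validate()


def filter_variants(
    table: VariantTable, maf_min: float = 0.02, call_rate_min: float = 0.80
) -> VariantTable:
    """MAF / call-rate filter (MAF strictly greater; call rate at least).

    MAF is computed over all samples called at the site, counting alleles
    diploid. Removal counts are logged by reason.
    """
    if not (0 <= maf_min <= 1 and 0 <= call_rate_min <= 1):
        raise ValidationError("thresholds must lie in [0,1]")
    if table.n_sites == 0:
        log.warning("filter_variants: empty input table")
        return table
    g = table.genotypes.to_numpy()
    called = g != MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / g.shape[1]
    alt_alleles = np.where(called, g, 0).sum(axis=1)  # codes are alt-dosage
    total_alleles = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(total_alleles > 0, alt_alleles / total_alleles, 0.0)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    pass_rate = call_rate >= call_rate_min
    pass_maf = maf > maf_min
    keep = pass_rate & pass_maf
    log.info(
        "filter_variants: removed %d by call rate, %d by MAF, kept %d/%d",
        int((~pass_rate).sum()),
        int((pass_rate & ~pass_maf).sum()),
        int(keep.sum()),
        len(keep),
    )
    return VariantTable(
        table.sites[keep],
        table.genotypes[keep],
        donors=table.donors,
        recipients=table.recipients,
    )


def extract_region_variants(table: VariantTable, registry: list[QTLRegion]) -> VariantTable:
    """Restrict to sites inside a QTL window (inclusive bounds) and annotate
    each retained site with its ``region_id``."""
    region_ids = []
    keep = np.zeros(table.n_sites, dtype=bool)
    for i, site in enumerate(table.sites.itertuples(index=False)):
        for r in registry:
            if r.contains(site.chrom, site.pos):
                keep[i] = True
                region_ids.append(r.id)
                break
    sites = table.sites[keep].reset_index(drop=True)
    sites = sites.assign(region_id=region_ids)
    return VariantTable(
        sites, table.genotypes[keep], donors=table.donors, recipients=table.recipients
    )


def find_donor_specific(
    table: VariantTable,
    donor_id: str,
    recipient_ids: list[str],
    registry: list[QTLRegion] | None = None,
) -> list[CandidateSNP]:
    """Donor-specific SNPs with their recipient-background utility sets.

    A recipient joins the utility set only when it is homozygous for an
    allele different from the donor's homozygous allele. Donor-heterozygous
    or donor-missing sites are skipped; sites with an empty utility set are
    excluded.
    """
    if donor_id not in table.samples:
        raise ValidationError(f"donor {donor_id} not in table")
    for r in recipient_ids:
        if r not in table.samples:
            raise ValidationError(f"recipient {r} not in table")
    has_region = "region_id" in table.sites.columns
    donor_gt = table.genotypes[donor_id].to_numpy()
    rec_gt = table.genotypes[recipient_ids].to_numpy()
    out: list[CandidateSNP] = []
    n_skipped_het = 0
    for i, site in enumerate(table.sites.itertuples(index=False)):
        d = donor_gt[i]
        if d not in (HOM_REF, HOM_ALT):
            n_skipped_het += 1
            continue
        opposite = HOM_ALT if d == HOM_REF else HOM_REF
        utility = frozenset(
            rid for rid, g in zip(recipient_ids, rec_gt[i]) if g == opposite
        )
        if not utility:
            continue
        region_id = getattr(site, "region_id", None) if has_region else None
        if region_id is None and registry is not None:
            region_id = next(
                (r.id for r in registry if r.contains(site.chrom, site.pos)), None
            )
        donor_allele = site.alt if d == HOM_ALT else site.ref
        out.append(
            CandidateSNP(
                chromosome=str(site.chrom),
                position_bp=int(site.pos),
                ref_allele=site.ref,
                donor_allele=donor_allele,
                donor_id=donor_id,
                utility_set=utility,
                region_id=region_id or "",
                alt_allele=site.alt,
            )
        )
    if n_skipped_het:
        log.info(
            "find_donor_specific(%s): skipped %d donor-het/missing sites",
            donor_id, n_skipped_het,
        )
    return out


def candidates_to_frame(candidates: list[CandidateSNP]) -> pd.DataFrame:
    """Candidate list as the CSV-ready frame (utility semicolon-joined)."""
    return pd.DataFrame(
        [
            dict(
                marker_id=c.marker_id,
                chrom=c.chromosome,
                pos=c.position_bp,
                ref=c.ref_allele,
                positive_allele=c.donor_allele,
                donor=c.donor_id,
                utility_set=";".join(sorted(c.utility_set)),
                region_id=c.region_id,
            )
            for c in candidates
        ]
    )
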