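"""Core in-memory containers shared across the pipeline.

Genotypes are coded as small integers throughout:

====  =============================
code  meaning
====  =============================
0     homozygous reference allele
1     heterozygous
2     homozygous alternate allele
-1    missing / no-call
====  =============================

In progeny matrices the same coding is read against the *donor* allele:
0 = recipient-homozygous, 1 = heterozygous, 2 = donor-homozygous.
Coordinates are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
GT_CODES = {v: k for k, v in GT_STRINGS.items()}
GT_CODES["1/0"] = HET
GT_CODES["./1"] = MISSING
GT_CODES["0/."] = MISSING


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class IntegrityError(RuntimeError):
    """Raised when a packaged data file fails its checksum."""


@dataclass(frozen=True)
class QTLRegion:
    """A published QTL window on one chromosome (1-based inclusive bp)."""

    id: str
    chromosome: str
    start_bp: int
    end_bp: int
    trait: str = ""

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise ValidationError(
                f"region {self.id}: start_bp {self.start_bp} must be < end_bp {self.end_bp}"
            )

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return (
            str(chromosome) == self.chromosome
            and self.start_bp <= position_bp <= self.end_bp
        )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class VariantTable:
    """Multi-sample biallelic SNP table.

    ``sites`` has columns chrom, pos, ref, alt (one row per SNP);
    ``genotypes`` is an int8 frame aligned row-for-row with ``sites``
    whose columns are sample ids.
    """

    sites: pd.DataFrame
    genotypes: pd.DataFrame
    donors: list[str] = field(default_factory=list)
    recipients: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = self.genotypes.reset_index(drop=True).astype(np.int8)
        if len(self.sites) != len(self.genotypes):
            raise ValidationError("sites and genotypes row counts differ")
        if self.genotypes.columns.duplicated().any():
            dupes = self.genotypes.columns[self.genotypes.columns.duplicated()]
            raise ValidationError(f"duplicate sample ids: {sorted(set(dupes))}")

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self) -> "VariantTable":
        """Check biallelic-SNP and position-ordering invariants."""
        bases = {"A", "C", "G", "T"}
        for col in ("ref", "alt"):
            bad = ~self.sites[col].isin(bases)
            if bad.any():
                raise ValidationError(
                    f"non-SNP alleles in column {col}: rows {list(self.sites.index[bad][:5])}"
                )
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValidationError(
                    f"positions on chromosome {chrom} not strictly increasing"
                )
        return self

    def sorted(self) -> "VariantTable":
        order = self.sites.sort_values(["chrom", "pos"]).index
        return VariantTable(
            self.sites.loc[order],
            self.genotypes.loc[order],
            donors=list(self.donors),
            recipients=list(self.recipients),
        )

    def site_keys(self) -> pd.Index:
        return pd.Index(zip(self.sites["chrom"], self.sites["pos"]))


@dataclass(frozen=True)
class CandidateSNP:
    """A donor-specific SNP eligible for KASP assay design.

    The donor allele is the "positive" allele: present homozygously in the
    donor and absent from every recipient in ``utility_set``.
    """

    chromosome: str
    position_bp: int
    ref_allele: str
    donor_allele: str
    donor_id: str
    utility_set: frozenset[str]
    region_id: str
    alt_allele: str = ""  # site alternate allele (donor_allele may equal ref)

    @property
    def marker_id(self) -> str:
        return f"K_{self.position_bp}"


@dataclass
class MarkerAssay:
    """One candidate KASP assay with its primers and specificity verdict."""

    candidate: CandidateSNP
    bracket_sequence: str = ""
    primer_allele_ref: str = ""
    primer_allele_alt: str = ""
    primer_common: str = ""
    amplicon_length: int = 0
    tm_ref: float = float("nan")
    tm_alt: float = float("nan")
    tm_common: float = float("nan")
    specificity_hits: int = 0
    status: str = "pending"  # accepted | rejected_multilocus | rejected_design
    truncated_flank: bool = False


@dataclass
class GenotypeMatrix:
    """Marker x progeny calls, optionally with simulation truth.

    ``calls`` and ``truth`` are progeny-by-marker int8 frames (rows indexed
    by progeny id, columns by marker id); ``populations`` maps progeny id to
    population id.
    """

    calls: pd.DataFrame
    truth: pd.DataFrame | None = None
    populations: pd.Series | None = None

    def __post_init__(self):
        self.calls = self.calls.astype(np.int8)
        if self.truth is not None:
            self.truth = self.truth.astype(np.int8)
            if not self.truth.index.equals(self.calls.index) or not (
                self.truth.columns.equals(self.calls.columns)
            ):
                raise ValidationError("truth and calls must share index/columns")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def progeny(self) -> list[str]:
        return list(self.calls.index)
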