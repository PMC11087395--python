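"""Standard-format readers and writers plus the packaged reference tables.

VCF access goes through pysam; FASTA through Biopython/pyfaidx. Two data
files ship with the package: the 54-marker reference KASP panel for
deep-sown direct-seeded rice (a curated transcription of the published
quality-control table, checksummed) and the default QTL-window registry.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .datamodel import (
    GT_CODES,
    GT_STRINGS,
    MISSING,
    IntegrityError,
    QTLRegion,
    ValidationError,
    VariantTable,
)

log = logging.getLogger(__name__)

PANEL54_SHA256 = "44a1258f2e9a3c0bd62e02360ab52e544afbb403cf4e327f28e84e9966b9b3de"

_BASES = {"A", "C", "G", "T"}


def _gt_code(gt_tuple) -> int:
    if gt_tuple is None:
        return MISSING
    alleles = [a for a in gt_tuple if a is not None]
    if len(alleles) < 2:
        return MISSING
    return int(alleles[0]) + int(alleles[1])


def read_vcf(path, donors=None, recipients=None) -> VariantTable:
    """Read a VCF v4.x into a :class:`VariantTable`.

    Non-SNP and multiallelic records are dropped (counts logged); genotypes
    map onto {0/0, 0/1, 1/1, missing} via the GT subfield only.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    rows, geno = [], []
    n_dropped_multi = n_dropped_nonsnp = 0
    for lineno, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        if len(alts) != 1:
            n_dropped_multi += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            n_dropped_nonsnp += 1
            continue
        try:
            codes = [_gt_code(rec.samples[s].get("GT")) for s in samples]
        except (KeyError, ValueError) as exc:
            raise ValidationError(f"malformed record at {path} data line {lineno}: {exc}")
        rows.append((rec.chrom, rec.pos, ref, alt))
        geno.append(codes)
    if n_dropped_multi or n_dropped_nonsnp:
        log.info(
            "read_vcf(%s): dropped %d multiallelic and %d non-SNP records",
            path, n_dropped_multi, n_dropped_nonsnp,
        )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gmat = pd.DataFrame(geno, columns=samples, dtype=np.int8)
    return VariantTable(
        sites, gmat, donors=list(donors or []), recipients=list(recipients or [])
    ).validate()


def write_vcf(table: VariantTable, path, contig_lengths: dict[str, int] | None = None):
    """Write a :class:`VariantTable` as uncompressed VCF v4.2 (GT only)."""
    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = list(dict.fromkeys(table.sites["chrom"]))
    for chrom in chroms:
        length = None if contig_lengths is None else contig_lengths.get(chrom)
        if length is None:
            length = int(table.sites.loc[table.sites["chrom"] == chrom, "pos"].max()) + 1
        header.contigs.add(str(chrom), length=int(length))
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        gvals = table.genotypes.to_numpy()
        for i, site in enumerate(table.sites.itertuples(index=False)):
            rec = out.new_record(
                contig=str(site.chrom),
                start=int(site.pos) - 1,
                stop=int(site.pos),
                alleles=(site.ref, site.alt),
            )
            for j, s in enumerate(table.samples):
                code = int(gvals[i, j])
                if code == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    gt = GT_STRINGS[code]
                    rec.samples[s]["GT"] = tuple(int(a) for a in gt.split("/"))
            out.write(rec)
    return path


def load_qtl_registry(config_path=None) -> list[QTLRegion]:
    """Load the QTL-window registry; with no argument, the packaged default.

    Bounds may be given in Mb (``start_mb``/``end_mb``, converted as
    Mb x 10^6) or directly in bp. Overlapping windows on one chromosome are
    a validation error.
    """
    if config_path is None:
        text = resources.files("kaspanel.data").joinpath("qtl_regions.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    doc = yaml.safe_load(text)
    if not doc or "regions" not in doc or not doc["regions"]:
        raise ValidationError("QTL registry is empty or missing a 'regions' list")
    regions = []
    for item in doc["regions"]:
        if "start_mb" in item:
            start = int(round(float(item["start_mb"]) * 1_000_000))
            end = int(round(float(item["end_mb"]) * 1_000_000))
        else:
            start, end = int(item["start_bp"]), int(item["end_bp"])
        regions.append(
            QTLRegion(
                id=str(item["id"]),
                chromosome=str(item["chromosome"]),
                start_bp=start,
                end_bp=end,
                trait=str(item.get("trait", "")),
            )
        )
    by_chrom: dict[str, list[QTLRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start_bp)
        for a, b in zip(rs, rs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValidationError(
                    f"regions {a.id} and {b.id} overlap on chromosome {chrom}"
                )
    return regions


def load_table3(path=None) -> pd.DataFrame:
    """Load the packaged 54-marker reference panel table.

    The table carries, per marker: locus and alleles, the recipient
    backgrounds it is informative against (utility), FPR/FNR and allele-class
    counts/means in two validation population classes, and the
    Kruskal-Wallis significance tier. The two population classes are labelled
    A and B as printed; internal consistency of sample sizes identifies A
    with the BC3F2:3 material (n up to 713) and B with the F3:F4 material
    (n up to 256). Printed irregularities are preserved and flagged in the
    ``provenance_flags`` column.
    """
    if path is None:
        ref = resources.files("kaspanel.data").joinpath("kasp_panel54.csv")
        raw = ref.read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != PANEL54_SHA256:
            raise IntegrityError(
                f"packaged panel table checksum mismatch: {digest} != {PANEL54_SHA256}"
            )
        import io as _io

        df = pd.read_csv(_io.BytesIO(raw), keep_default_na=False)
    else:
        df = pd.read_csv(path, keep_default_na=False)
    if len(df) != 54:
        raise IntegrityError(f"expected 54 panel rows, found {len(df)}")
    df["chromosome"] = df["chromosome"].astype(str)
    return df


def load_core_panel(path=None) -> list[str]:
    """Return the pinned 12-assay core-panel marker ids."""
    if path is None:
        text = resources.files("kaspanel.data").joinpath("core_panel12.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    ids = list(doc["marker_ids"])
    if len(ids) != len(set(ids)):
        raise ValidationError("core panel contains duplicate marker ids")
    return ids


def write_fasta(sequences: dict[str, str], path):
    """Write chromosome sequences as uncompressed FASTA (60-column wrap)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def genotype_calls_to_strings(frame: pd.DataFrame) -> pd.DataFrame:
    """Render an int-coded genotype frame with VCF-style strings."""
    return frame.replace({c: s for c, s in GT_STRINGS.items()})


def genotype_strings_to_calls(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.replace(GT_CODES)
    return out.astype(np.int8)
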