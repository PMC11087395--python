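"""KASP assay construction: flank extraction, bracketed-SNP formatting,
allele-specific primer design with fluorophore tails, melting temperatures
and multi-locus specificity rejection.

The two allele-specific forward primers end exactly on the SNP base and
differ only there (plus their 5' tails); a common reverse primer on the
opposite strand closes an amplicon within the configured bounds. Multi-locus
screening counts exact genomic occurrences (both strands) of the 3'-anchored
primer core; more than one hit rejects the assay. Melting temperatures come
from Biopython's Wallace rule or unified nearest-neighbor stack, tails
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from .datamodel import CandidateSNP, MarkerAssay, ValidationError

log = logging.getLogger(__name__)

# Widely published fluorophore tail oligos for the two allele-specific primers.
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class DesignParams:
    primer_len_min: int = 18
    primer_len_max: int = 28
    tm_min: float = 57.0
    tm_max: float = 63.0
    tm_target: float = 60.0
    amplicon_min: int = 50
    amplicon_max: int = 120
    tail_ref: str = FAM_TAIL
    tail_alt: str = HEX_TAIL
    tm_method: str = "nearest_neighbor"  # or "wallace"
    specificity_core_len: int = 16
    specificity_mismatches: int = 0
    flank_len: int = 100


def melting_temperature(oligo: str, method: str = "wallace") -> float:
    """Melting temperature of an untailed oligo in degrees Celsius.

    ``wallace`` is the 2(A+T) + 4(G+C) rule; ``nearest_neighbor`` the
    unified-parameter stack model at Biopython's default oligo/salt
    concentrations.
    """
    oligo = oligo.upper()
    if not oligo or any(b not in "ACGT" for b in oligo):
        raise ValidationError(f"non-ACGT oligo: {oligo!r}")
    if method == "wallace":
        return float(_mt.Tm_Wallace(Seq(oligo)))
    if method == "nearest_neighbor":
        return float(_mt.Tm_NN(Seq(oligo)))
    raise ValidationError(f"unknown Tm method {method!r}")


def extract_flanks(
    candidate: CandidateSNP, reference: dict[str, str], flank_len: int = 100
) -> tuple[str, bool]:
    """Bracketed design sequence: upstream + ``[ref/alt]`` + downstream.

    Returns (bracket_sequence, truncated_flag); flanks shorter than
    ``flank_len`` at chromosome ends are truncated and flagged.
    """
    chrom = reference.get(candidate.chromosome)
    if chrom is None:
        raise ValidationError(f"chromosome {candidate.chromosome} absent from reference")
    pos = candidate.position_bp
    if not 1 <= pos <= len(chrom):
        raise ValidationError(
            f"position {pos} outside chromosome {candidate.chromosome} (len {len(chrom)})"
        )
    ref_base = chrom[pos - 1]
    if ref_base != candidate.ref_allele:
        raise ValidationError(
            f"reference base {ref_base} at {candidate.chromosome}:{pos} "
            f"does not match candidate ref allele {candidate.ref_allele}"
        )
    left = chrom[max(0, pos - 1 - flank_len) : pos - 1]
    right = chrom[pos : pos + flank_len]
    truncated = len(left) < flank_len or len(right) < flank_len
    alt = candidate.alt_allele or candidate.donor_allele
    if alt == candidate.ref_allele or not alt:
        raise ValidationError("candidate has no alternate allele distinct from the reference")
    bracket = f"{left}[{candidate.ref_allele}/{alt}]{right}"
    return bracket, truncated


def parse_bracket(bracket_sequence: str) -> tuple[str, str, str, str]:
    """Inverse of :func:`extract_flanks`: (left, ref, alt, right)."""
    try:
        left, rest = bracket_sequence.split("[", 1)
        alleles, right = rest.split("]", 1)
        ref, alt = alleles.split("/")
    except ValueError as exc:
        raise ValidationError(f"malformed bracket sequence: {bracket_sequence[:40]}...") from exc
    return left, ref, alt, right


def format_design_input(assays: list[MarkerAssay]) -> pd.DataFrame:
    """Design-input table: one row per candidate (id, chromosome, bracket)."""
    if not assays:
        log.warning("format_design_input: empty candidate list")
    return pd.DataFrame(
        [
            dict(
                id=a.candidate.marker_id,
                chromosome=a.candidate.chromosome,
                sequence=a.bracket_sequence,
            )
            for a in assays
        ],
        columns=["id", "chromosome", "sequence"],
    )


def _pick_allele_primer(left: str, allele: str, params: DesignParams):
    """Left-extend from the SNP base until Tm enters the window.

    Candidates are ranked by |Tm - target|, then shorter length. Returns
    (core_without_tail, tm) or None.
    """
    best = None
    for length in range(params.primer_len_min, params.primer_len_max + 1):
        need = length - 1
        if need > len(left):
            break
        core = left[len(left) - need :] + allele
        tm = melting_temperature(core, params.tm_method)
        if params.tm_min <= tm <= params.tm_max:
            key = (abs(tm - params.tm_target), length)
            if best is None or key < best[0]:
                best = (key, core, tm)
    if best is None:
        return None
    return best[1], best[2]


def _pick_common_primer(right: str, params: DesignParams):
    """Reverse-strand common primer within the amplicon bounds.

    The amplicon runs from the allele-specific primer's 3' SNP base to the
    common primer's far end. Ties break by |Tm - target|, then length, then
    leftmost position.
    """
    best = None
    for end in range(params.amplicon_min, min(params.amplicon_max, len(right) + 1) + 1):
        # common primer covers reference plus-strand interval [start, end) of `right`
        for length in range(params.primer_len_min, params.primer_len_max + 1):
            start = end - length
            if start < 0:
                break
            plus = right[start:end]
            primer = _revcomp(plus)
            tm = melting_temperature(primer, params.tm_method)
            if params.tm_min <= tm <= params.tm_max:
                amplicon_length = end + 1  # + the SNP base itself
                key = (abs(tm - params.tm_target), length, start)
                if best is None or key < best[0]:
                    best = (key, primer, tm, amplicon_length)
    if best is None:
        return None
    return best[1], best[2], best[3]


def design_primers(assay: MarkerAssay, params: DesignParams = DesignParams()) -> MarkerAssay:
    """Fill the primer fields of an assay from its bracket sequence."""
    left, ref, alt, right = parse_bracket(assay.bracket_sequence)
    ref_pick = _pick_allele_primer(left, ref, params)
    alt_pick = _pick_allele_primer(left, alt, params)
    common_pick = _pick_common_primer(right, params)
    if ref_pick is None or alt_pick is None or common_pick is None:
        assay.status = "rejected_design"
        return assay
    # allele-specific primers share the same core length: redo the shorter one
    # at the longer's length so the pair differs only at the 3' base
    core_len = max(len(ref_pick[0]), len(alt_pick[0]))
    need = core_len - 1
    if need <= len(left):
        ref_core = left[len(left) - need :] + ref
        alt_core = left[len(left) - need :] + alt
        tm_ref = melting_temperature(ref_core, params.tm_method)
        tm_alt = melting_temperature(alt_core, params.tm_method)
        if not (params.tm_min <= tm_ref <= params.tm_max and params.tm_min <= tm_alt <= params.tm_max):
            # fall back to the individually optimal picks
            ref_core, tm_ref = ref_pick
            alt_core, tm_alt = alt_pick
    else:
        ref_core, tm_ref = ref_pick
        alt_core, tm_alt = alt_pick
    primer_common, tm_common, amplicon = common_pick
    assay.primer_allele_ref = params.tail_ref + ref_core
    assay.primer_allele_alt = params.tail_alt + alt_core
    assay.primer_common = primer_common
    assay.tm_ref = tm_ref
    assay.tm_alt = tm_alt
    assay.tm_common = tm_common
    assay.amplicon_length = amplicon
    assay.status = "designed"
    return assay


def count_genomic_hits(core: str, reference: dict[str, str], mismatches: int = 0) -> int:
    """Occurrences of ``core`` in the reference, both strands, overlapping."""
    total = 0
    rc = _revcomp(core)
    for seq in reference.values():
        for probe in (core, rc):
            if mismatches == 0:
                start = 0
                while True:
                    i = seq.find(probe, start)
                    if i < 0:
                        break
                    total += 1
                    start = i + 1
            else:
                k = len(probe)
                for i in range(len(seq) - k + 1):
                    window = seq[i : i + k]
                    if sum(a != b for a, b in zip(window, probe)) <= mismatches:
                        total += 1
    return total


def specificity_check(
    assay: MarkerAssay, reference: dict[str, str], params: DesignParams = DesignParams()
) -> MarkerAssay:
    """Count exact genomic matches of the allele-specific 3' cores.

    The core is the last ``specificity_core_len`` untailed bases of each
    allele-specific primer, searched on both strands of the reference (which
    carries the ref allele). More than one hit for either primer rejects the
    assay as multi-locus; exactly one hit of the reference-allele core
    accepts it. The alternate-allele core legitimately has zero hits (its 3'
    base mismatches the reference at the target locus).
    """
    if params.specificity_core_len < 12:
        raise ValidationError("specificity core must be at least 12 nt")
    if assay.status == "rejected_design":
        return assay
    core_len = params.specificity_core_len
    ref_core = assay.primer_allele_ref[len(params.tail_ref) :][-core_len:]
    alt_core = assay.primer_allele_alt[len(params.tail_alt) :][-core_len:]
    hits_ref = count_genomic_hits(ref_core, reference, params.specificity_mismatches)
    hits_alt = count_genomic_hits(alt_core, reference, params.specificity_mismatches)
    assay.specificity_hits = max(hits_ref, hits_alt)
    if hits_ref > 1 or hits_alt > 1:
        assay.status = "rejected_multilocus"
    elif hits_ref == 1:
        assay.status = "accepted"
    else:
        # the designed locus could not be re-located: defensive rejection
        assay.status = "rejected_design"
    return assay


def design_assays(
    candidates: list[CandidateSNP],
    reference: dict[str, str],
    params: DesignParams = DesignParams(),
) -> list[MarkerAssay]:
    """Full design stage: flanks, primers, specificity, per-criterion tally."""
    assays = []
    tally = {"designed": 0, "rejected_design": 0, "rejected_multilocus": 0, "accepted": 0}
    for cand in candidates:
        assay = MarkerAssay(candidate=cand)
        bracket, truncated = extract_flanks(cand, reference, params.flank_len)
        assay.bracket_sequence = bracket
        assay.truncated_flank = truncated
        assay = design_primers(assay, params)
        if assay.status != "rejected_design":
            assay = specificity_check(assay, reference, params)
        tally[assay.status] = tally.get(assay.status, 0) + 1
        assays.append(assay)
    log.info("design_assays: %s", tally)
    return assays


def assays_to_frame(assays: list[MarkerAssay]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                marker_id=a.candidate.marker_id,
                chrom=a.candidate.chromosome,
                pos=a.candidate.position_bp,
                ref=a.candidate.ref_allele,
                positive_allele=a.candidate.donor_allele,
                primer_allele_ref=a.primer_allele_ref,
                primer_allele_alt=a.primer_allele_alt,
                primer_common=a.primer_common,
                amplicon_length=a.amplicon_length,
                tm_ref=a.tm_ref,
                tm_alt=a.tm_alt,
                tm_common=a.tm_common,
                specificity_hits=a.specificity_hits,
                status=a.status,
            )
            for a in assays
        ]
    )
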