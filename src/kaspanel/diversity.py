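"""Parent-level genetic relationships and SNP functional context.

Distance is the simple mismatch proportion over shared non-missing sites;
trees come from UPGMA (arithmetic-mean linkage, deterministic lexicographic
tie-breaks, ultrametric Newick output); ordination is a plain PCA of the
0/1/2-coded genotype matrix. Variants are classified against gene models
with the precedence CDS > UTR > intron > intergenic, and CDS variants are
labelled synonymous / missense / other by translating the reference and
alternate codons (strand-aware) under the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .datamodel import MISSING, ValidationError, VariantTable


# ---------------------------------------------------------------------------
# distances, UPGMA, PCA


def genotype_distance(table: VariantTable) -> pd.DataFrame:
    """Pairwise genotype mismatch proportion over shared non-missing sites."""
    if len(table.samples) < 2:
        raise ValidationError("need at least 2 samples")
    g = table.genotypes.to_numpy()
    samples = table.samples
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (g[:, i] != MISSING) & (g[:, j] != MISSING)
            if shared.sum() == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = float(
                    (g[shared, i] != g[shared, j]).mean()
                )
    return pd.DataFrame(d, index=samples, columns=samples)


def upgma(matrix: pd.DataFrame) -> str:
    """UPGMA agglomeration to a rooted ultrametric Newick string.

    Cluster heights are half the merge distance; ties break by the
    lexicographically smallest member label, so the output is deterministic.
    """
    labels = list(matrix.index)
    if list(matrix.columns) != labels:
        raise ValidationError("distance matrix must be square with matching labels")
    d = {frozenset((a, b)): float(matrix.loc[a, b]) for a in labels for b in labels if a != b}
    # cluster state: key -> (newick, height, size, min_label)
    clusters = {a: (a, 0.0, 1, a) for a in labels}
    dist = {k: v for k, v in d.items()}
    while len(clusters) > 1:
        # nearest pair; ties resolved by sorted (min_label_a, min_label_b)
        best = None
        for key, val in dist.items():
            a, b = sorted(key, key=lambda c: clusters[c][3])
            tie = (val, clusters[a][3], clusters[b][3])
            if best is None or tie < best[0]:
                best = (tie, a, b)
        _, a, b = best
        val = dist[frozenset((a, b))]
        na, nb = clusters[a][2], clusters[b][2]
        height = val / 2.0
        newick = (
            f"({clusters[a][0]}:{height - clusters[a][1]:.12g},"
            f"{clusters[b][0]}:{height - clusters[b][1]:.12g})"
        )
        new_key = f"__{a}__{b}__"
        min_label = min(clusters[a][3], clusters[b][3])
        # arithmetic-mean update
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_key, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[new_key] = (newick, height, na + nb, min_label)
    (newick, height, size, _), = clusters.values()
    return newick + ";"


def tree_leaf_depths(newick: str) -> dict[str, float]:
    """Root-to-tip path lengths of a Newick tree (ultrametry check)."""
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(newick), "newick")
    return {
        leaf.name: tree.distance(tree.root, leaf) for leaf in tree.get_terminals()
    }


def pca_coordinates(table: VariantTable, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the leading principal components.

    Genotypes are 0/1/2 coded with missing values mean-imputed per site;
    zero-variance sites are dropped; scores come from the SVD of the
    column-centered matrix. Returns (scores, explained_variance_fractions).
    """
    g = table.genotypes.to_numpy(float).T  # samples x sites
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    g = g - g.mean(axis=0)
    keep = g.std(axis=0) > 0
    g = g[:, keep]
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=table.samples,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return scores, explained[:k]


# ---------------------------------------------------------------------------
# gene models and functional context


@dataclass
class GeneModel:
    """One gene with exon/CDS/UTR intervals (1-based inclusive)."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Flat GFF3 reader for gene/exon/CDS/UTR features keyed by gene id."""
    genes: dict[str, GeneModel] = {}
    parent_gene: dict[str, str] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValidationError(f"malformed GFF3 line: {line[:60]}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            a = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start, end = int(start), int(end)
            if ftype == "gene":
                gid = a.get("ID", f"gene_{len(genes)}")
                genes[gid] = GeneModel(gid, chrom, strand, start, end)
            elif ftype == "mRNA":
                gid = a.get("Parent")
                if gid in genes:
                    parent_gene[a.get("ID", "")] = gid
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a.get("Parent", "")
                gid = parent_gene.get(parent, parent)
                if gid not in genes:
                    continue
                if ftype == "exon":
                    genes[gid].exons.append((start, end))
                elif ftype == "CDS":
                    genes[gid].cds.append((start, end))
                else:
                    genes[gid].utrs.append((start, end))
    for g in genes.values():
        g.exons.sort()
        g.cds.sort()
        g.utrs.sort()
    return list(genes.values())


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def classify_variant_context(
    chromosome: str, position_bp: int, gene_models: list[GeneModel]
) -> str:
    """One of intergenic / intron / UTR / CDS with CDS > UTR > intron
    precedence across overlapping models."""
    best = "intergenic"
    rank = {"intergenic": 0, "intron": 1, "UTR": 2, "CDS": 3}
    for g in gene_models:
        if g.chromosome != chromosome or not (g.start <= position_bp <= g.end):
            continue
        if _in_intervals(position_bp, g.cds):
            label = "CDS"
        elif _in_intervals(position_bp, g.utrs):
            label = "UTR"
        else:
            label = "intron"
        if rank[label] > rank[best]:
            best = label
    return best


def coding_effect(
    chromosome: str,
    position_bp: int,
    ref_allele: str,
    alt_allele: str,
    gene_model: GeneModel,
    reference: dict[str, str],
) -> str:
    """synonymous / missense / other for a CDS SNP of a complete model.

    The codon is located by CDS coordinate arithmetic; on minus-strand genes
    the alleles are complemented and the CDS read 3'->5' along the plus
    strand. Stop gain or loss maps to "other".
    """
    if gene_model.cds_length() % 3 != 0:
        raise ValidationError(
            f"gene {gene_model.gene_id}: CDS length {gene_model.cds_length()} not divisible by 3"
        )
    if not _in_intervals(position_bp, gene_model.cds):
        raise ValidationError("variant does not fall in the model's CDS")
    chrom_seq = reference[chromosome]
    if chrom_seq[position_bp - 1] != ref_allele:
        raise ValidationError("reference allele mismatch at the variant position")
    # CDS offset in transcription order
    if gene_model.strand == "+":
        offset = 0
        for s, e in gene_model.cds:
            if s <= position_bp <= e:
                offset += position_bp - s
                break
            offset += e - s + 1
        cds_seq = "".join(chrom_seq[s - 1 : e] for s, e in gene_model.cds)
        ref_base, alt_base = ref_allele, alt_allele
    else:
        offset = 0
        for s, e in reversed(gene_model.cds):
            if s <= position_bp <= e:
                offset += e - position_bp
                break
            offset += e - s + 1
        cds_seq = str(
            Seq("".join(chrom_seq[s - 1 : e] for s, e in gene_model.cds)).reverse_complement()
        )
        ref_base = str(Seq(ref_allele).complement())
        alt_base = str(Seq(alt_allele).complement())
    if cds_seq[offset] != ref_base:
        raise ValidationError("CDS sequence inconsistent with reference allele")
    codon_i = offset // 3
    within = offset % 3
    codon_ref = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if "*" in (aa_ref, aa_alt):
        return "other"
    return "missense"
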