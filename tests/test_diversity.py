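"""Distances, UPGMA, PCA and variant functional annotation."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from kaspanel import diversity
from kaspanel.datamodel import MISSING, ValidationError, VariantTable

from conftest import random_variant_table


class TestDistance:
    def test_identical_samples_zero(self):
        sites = pd.DataFrame({"chrom": "1", "pos": range(1, 11), "ref": "A", "alt": "T"})
        geno = pd.DataFrame({"A": [0, 1, 2] * 3 + [0], "B": [0, 1, 2] * 3 + [0]})
        d = diversity.genotype_distance(VariantTable(sites, geno))
        assert d.loc["A", "B"] == 0.0

    def test_fully_discordant_pair(self):
        sites = pd.DataFrame({"chrom": "1", "pos": range(1, 11), "ref": "A", "alt": "T"})
        geno = pd.DataFrame({"A": [0] * 10, "B": [2] * 10})
        d = diversity.genotype_distance(VariantTable(sites, geno))
        assert d.loc["A", "B"] == 1.0

    def test_matches_double_loop_oracle(self, rng):
        t = random_variant_table(rng, n_sites=100, samples=tuple("ABCDE"))
        d = diversity.genotype_distance(t)
        g = t.genotypes.to_numpy()
        for i, a in enumerate(t.samples):
            for j, b in enumerate(t.samples):
                if i == j:
                    assert d.loc[a, b] == 0.0
                    continue
                mism = tot = 0
                for k in range(t.n_sites):
                    if g[k, i] != MISSING and g[k, j] != MISSING:
                        tot += 1
                        mism += g[k, i] != g[k, j]
                assert d.loc[a, b] == pytest.approx(mism / tot)


def brute_force_upgma(matrix: pd.DataFrame) -> dict:
    """Independent UPGMA: returns merge heights per cluster frozenset."""
    clusters = {frozenset([l]): 0.0 for l in matrix.index}
    d = {
        frozenset([a, b]): matrix.loc[a, b]
        for a in matrix.index
        for b in matrix.index
        if a != b
    }
    active = [frozenset([l]) for l in matrix.index]
    heights = {}

    def dist(x, y):
        vals = [matrix.loc[a, b] for a in x for b in y]
        return sum(vals) / len(vals)

    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                dd = dist(active[i], active[j])
                key = (dd, min(active[i]), min(active[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = active[i] | active[j]
        heights[merged] = dist(active[i], active[j]) / 2.0
        active = [c for k, c in enumerate(active) if k not in (i, j)] + [merged]
    return heights


class TestUPGMA:
    def test_hand_agglomeration(self):
        m = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        assert diversity.upgma(m) == "((A:1,B:1):1,C:2);"

    def test_two_taxa_cherry(self):
        m = pd.DataFrame([[0, 3], [3, 0]], index=["X", "Y"], columns=["X", "Y"], dtype=float)
        assert diversity.upgma(m) == "(X:1.5,Y:1.5);"

    def test_output_is_ultrametric(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 6))
            labels = [f"t{i}" for i in range(n)]
            a = rng.integers(1, 20, size=(n, n)).astype(float)
            m = pd.DataFrame((a + a.T) / 2, index=labels, columns=labels)
            np.fill_diagonal(m.values, 0.0)
            depths = diversity.tree_leaf_depths(diversity.upgma(m))
            vals = list(depths.values())
            assert max(vals) - min(vals) < 1e-9

    def test_matches_brute_force_heights(self, rng):
        """Merge heights agree with an independent all-pairs UPGMA on random
        matrices of up to 5 taxa."""
        for trial in range(10):
            n = int(rng.integers(3, 6))
            labels = [f"t{i}" for i in range(n)]
            a = rng.integers(1, 40, size=(n, n)).astype(float)
            m = pd.DataFrame((a + a.T) / 2, index=labels, columns=labels)
            np.fill_diagonal(m.values, 0.0)
            heights = sorted(brute_force_upgma(m).values())
            depths = diversity.tree_leaf_depths(diversity.upgma(m))
            # root depth equals the final (largest) merge height
            assert max(depths.values()) == pytest.approx(max(heights))

    def test_donor_recipient_groups_are_monophyletic(self, desk_dataset):
        """Synthetic parents cluster into the donor and recipient groups."""
        import io as _io

        from Bio import Phylo

        parents = desk_dataset["parents"]
        d = diversity.genotype_distance(parents)
        tree = Phylo.read(_io.StringIO(diversity.upgma(d)), "newick")
        donors = set(parents.donors)
        root_children = tree.root.clades
        sides = [
            {leaf.name for leaf in clade.get_terminals()} for clade in root_children
        ]
        assert any(s == donors for s in sides) or any(
            s == set(parents.recipients) for s in sides
        )


class TestPCA:
    def test_mirror_samples_symmetric_pc1(self):
        sites = pd.DataFrame({"chrom": "1", "pos": range(1, 21), "ref": "A", "alt": "T"})
        geno = pd.DataFrame({"A": [0, 2] * 10, "B": [2, 0] * 10})
        scores, _ = diversity.pca_coordinates(VariantTable(sites, geno), 1)
        assert scores.loc["A", "PC1"] == pytest.approx(-scores.loc["B", "PC1"])

    def test_explained_fractions_bounded(self, rng):
        t = random_variant_table(rng, 50, samples=tuple("ABCDEF"))
        _, frac = diversity.pca_coordinates(t, 3)
        assert frac.sum() <= 1.0 + 1e-12
        assert (np.diff(frac) <= 1e-12).all()

    def test_scores_match_svd_oracle(self, rng):
        t = random_variant_table(rng, 20, samples=tuple("ABCDE"))
        g = t.genotypes.to_numpy(float).T
        g[g == MISSING] = np.nan
        mu = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = np.take(mu, idx[1])
        g = g - g.mean(axis=0)
        g = g[:, g.std(axis=0) > 0]
        u, s, vt = np.linalg.svd(g, full_matrices=False)
        scores, _ = diversity.pca_coordinates(t, 2)
        for k in range(2):
            expected = u[:, k] * s[k]
            got = scores.iloc[:, k].to_numpy()
            assert np.allclose(got, expected, atol=1e-6) or np.allclose(
                got, -expected, atol=1e-6
            )


class TestContext:
    def make_models(self):
        g = diversity.GeneModel(
            "g1", "c", "+", 101, 400,
            exons=[(101, 200), (301, 400)],
            cds=[(131, 200), (301, 360)],
            utrs=[(101, 130), (361, 400)],
        )
        return [g]

    def test_precedence_labels(self):
        models = self.make_models()
        assert diversity.classify_variant_context("c", 150, models) == "CDS"
        assert diversity.classify_variant_context("c", 110, models) == "UTR"
        assert diversity.classify_variant_context("c", 250, models) == "intron"
        assert diversity.classify_variant_context("c", 50, models) == "intergenic"

    def test_every_position_gets_exactly_one_label(self, rng):
        models = self.make_models()
        labels = {"intergenic", "intron", "UTR", "CDS"}
        for pos in rng.integers(1, 500, size=200):
            assert diversity.classify_variant_context("c", int(pos), models) in labels

    def test_matches_interval_brute_force(self, rng):
        models = self.make_models()
        g = models[0]
        for pos in rng.integers(1, 500, size=1000):
            pos = int(pos)
            if not (g.start <= pos <= g.end):
                expect = "intergenic"
            elif any(s <= pos <= e for s, e in g.cds):
                expect = "CDS"
            elif any(s <= pos <= e for s, e in g.utrs):
                expect = "UTR"
            else:
                expect = "intron"
            assert diversity.classify_variant_context("c", pos, models) == expect


class TestCodingEffect:
    def _setup_plus(self, cds_seq, chrom_len=200, cds_start=31):
        ref = "A" * (cds_start - 1) + cds_seq + "G" * (chrom_len - cds_start + 1 - len(cds_seq))
        model = diversity.GeneModel(
            "g", "c", "+", cds_start, cds_start + len(cds_seq) - 1,
            exons=[(cds_start, cds_start + len(cds_seq) - 1)],
            cds=[(cds_start, cds_start + len(cds_seq) - 1)],
        )
        return {"c": ref}, model

    def test_synonymous_third_position(self):
        ref, model = self._setup_plus("GCAATG")  # Ala, Met
        # GCA -> GCG still Ala
        out = diversity.coding_effect("c", 33, "A", "G", model, ref)
        assert out == "synonymous"

    def test_missense_second_position(self):
        ref, model = self._setup_plus("ATGGCA")  # Met, Ala
        out = diversity.coding_effect("c", 32, "T", "C", model, ref)  # ATG->ACG Met->Thr
        assert out == "missense"

    def test_stop_gain_is_other(self):
        ref, model = self._setup_plus("TACATG")  # Tyr, Met
        out = diversity.coding_effect("c", 33, "C", "A", model, ref)  # TAC->TAA stop
        assert out == "other"

    def test_incomplete_cds_rejected(self):
        ref, model = self._setup_plus("GCAATG")
        model.cds = [(31, 34)]
        with pytest.raises(ValidationError):
            diversity.coding_effect("c", 33, "A", "G", model, ref)

    def test_exhaustive_codon_edit_oracle(self, rng):
        """All 9 single-base edits of random codons agree with direct
        translate-both comparison."""
        for _ in range(50):
            codon = "".join(rng.choice(list("ACGT"), size=3))
            ref, model = self._setup_plus(codon + "GGG")
            for within in range(3):
                pos = 31 + within
                base = codon[within]
                for alt in "ACGT":
                    if alt == base:
                        continue
                    got = diversity.coding_effect("c", pos, base, alt, model, ref)
                    alt_codon = codon[:within] + alt + codon[within + 1 :]
                    aa_ref = str(Seq(codon).translate())
                    aa_alt = str(Seq(alt_codon).translate())
                    if aa_ref == aa_alt:
                        expect = "synonymous"
                    elif "*" in (aa_ref, aa_alt):
                        expect = "other"
                    else:
                        expect = "missense"
                    assert got == expect

    def test_strand_consistency(self, rng):
        """A minus-strand gene over the reverse-complemented locus yields the
        same effect label as its plus-strand mirror."""
        for _ in range(20):
            cds = "ATG" + "".join(rng.choice(list("ACGT"), size=6))
            ref_plus, model_plus = self._setup_plus(cds)
            within = int(rng.integers(0, len(cds)))
            base = cds[within]
            alt = rng.choice([b for b in "ACGT" if b != base])
            plus_label = diversity.coding_effect(
                "c", 31 + within, base, alt, model_plus, ref_plus
            )
            # mirror: reverse-complement the chromosome, gene on minus strand
            chrom = ref_plus["c"]
            rc = str(Seq(chrom).reverse_complement())
            L = len(chrom)
            start, end = model_plus.cds[0]
            model_minus = diversity.GeneModel(
                "g", "c", "-", L - end + 1, L - start + 1,
                exons=[(L - end + 1, L - start + 1)],
                cds=[(L - end + 1, L - start + 1)],
            )
            pos_minus = L - (31 + within) + 1
            base_minus = str(Seq(base).complement())
            alt_minus = str(Seq(alt).complement())
            minus_label = diversity.coding_effect(
                "c", pos_minus, base_minus, alt_minus, model_minus, {"c": rc}
            )
            assert plus_label == minus_label


class TestGFF3:
    def test_read_gene_models(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1\n"
            "c\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1\n"
            "c\tsrc\texon\t101\t200\t.\t+\t.\tParent=t1\n"
            "c\tsrc\tCDS\t131\t200\t.\t+\t0\tParent=t1\n"
            "c\tsrc\tfive_prime_UTR\t101\t130\t.\t+\t.\tParent=t1\n"
        )
        (g,) = diversity.read_gene_models(gff)
        assert g.gene_id == "g1" and g.strand == "+"
        assert g.cds == [(131, 200)] and g.utrs == [(101, 130)]
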