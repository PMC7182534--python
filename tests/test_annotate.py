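"""Annotation assignment, closest-gene lookup, and contingency tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtiles import (
    AnnotationTrack,
    annotation_distribution_test,
    annotation_methylation_profile,
    assign_annotation,
    class_counts,
    closest_gene,
    closest_genes,
    tile_midpoints,
)


def iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture
def track():
    return AnnotationTrack(
        promoters=iv([("chr1", 100, 200), ("chr1", 900, 1000)]),
        exons=iv([("chr1", 150, 400), ("chr1", 600, 700)]),
        introns=iv([("chr1", 400, 600)]),
    )


class TestAssignAnnotation:
    def test_promoter_wins_over_exon(self, track):
        loci = pd.DataFrame({"chrom": ["chr1"], "pos": [160]})
        assert assign_annotation(loci, track)["klass"].iloc[0] == "promoter"

    def test_uncovered_is_intergenic(self, track):
        loci = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [5000, 10]})
        out = assign_annotation(loci, track)
        assert list(out["klass"]) == ["intergenic", "intergenic"]

    def test_classes_partition_loci(self, track, rng):
        loci = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 2000, size=300)})
        counts = class_counts(assign_annotation(loci, track))
        assert counts.sum() == 300

    def test_matches_bruteforce_membership_scan(self, rng):
        classes = {
            "promoter": [("chr1", int(s), int(s) + 50) for s in rng.integers(0, 950, 8)],
            "exon": [("chr1", int(s), int(s) + 80) for s in rng.integers(0, 900, 10)],
            "intron": [("chr1", int(s), int(s) + 120) for s in rng.integers(0, 850, 10)],
        }
        track = AnnotationTrack(
            promoters=iv(classes["promoter"]), exons=iv(classes["exon"]),
            introns=iv(classes["intron"]),
        )
        loci = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 1000, size=1000)})
        got = assign_annotation(loci, track)["klass"].to_numpy()
        for i, p in enumerate(loci["pos"]):
            expected = "intergenic"
            # precedence order: promoter beats exon beats intron
            for cls in ("promoter", "exon", "intron"):
                if any(s <= p < e for _, s, e in classes[cls]):
                    expected = cls
                    break
            assert got[i] == expected

    def test_interval_order_never_changes_assignment(self, rng):
        proms = [("chr1", 100, 300), ("chr1", 250, 500), ("chr1", 800, 900)]
        loci = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 1000, 200)})
        a = AnnotationTrack(iv(proms), iv([]), iv([]))
        b = AnnotationTrack(iv(proms[::-1]), iv([]), iv([]))
        pd.testing.assert_frame_equal(
            assign_annotation(loci, a), assign_annotation(loci, b)
        )

    def test_tile_midpoints(self):
        tiles = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [2000], "tile_id": ["t"]}
        )
        assert tile_midpoints(tiles)["pos"].iloc[0] == 1500


class TestClosestGene:
    # locus 350 is an exact tie: gap to A = 350-200+1 = 151, to B = 501-351+1 = 151
    GENES = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr2"], "start": [100, 501, 0],
         "end": [200, 601, 50], "name": ["A", "B", "C"]}
    )

    def test_containment(self):
        assert closest_gene("chr1", 150, None, self.GENES, 0) == "A"

    def test_tie_is_seeded_and_stable(self):
        # position 350 is equidistant between A (ends 200) and B (starts 500)
        picks = {closest_gene("chr1", 350, None, self.GENES, seed) for seed in range(20)}
        assert picks <= {"A", "B"} and len(picks) == 2
        first = closest_gene("chr1", 350, None, self.GENES, 7)
        assert all(closest_gene("chr1", 350, None, self.GENES, 7) == first for _ in range(5))

    def test_no_gene_on_chromosome(self):
        assert closest_gene("chrZ", 10, None, self.GENES, 0) is None

    def test_matches_exhaustive_distance_scan(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": (starts := np.sort(rng.choice(100_000, size=50, replace=False))),
                "end": starts + rng.integers(100, 2000, size=50),
                "name": [f"g{i}" for i in range(50)],
            }
        )
        loci = rng.integers(0, 110_000, size=500)
        for p in loci:
            got = closest_gene("chr1", int(p), None, genes, 0)
            dists = np.where(
                (genes["start"] < p + 1) & (p < genes["end"]),
                0, np.maximum(genes["start"] - (p + 1), p - genes["end"]) + 1,
            )
            best = set(genes["name"][dists == dists.min()])
            assert got in best

    def test_vectorised_wrapper_deterministic(self):
        loci = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [150, 350]})
        a = closest_genes(loci, self.GENES, seed=3)
        b = closest_genes(loci, self.GENES, seed=3)
        pd.testing.assert_series_equal(a, b)


class TestDistributionTest:
    def test_identical_proportions_give_zero_statistic(self):
        res = annotation_distribution_test([10, 20, 30], [20, 40, 60])
        assert res.statistic == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_2x2_hand_computed_pearson(self):
        # table (12,5 / 3,14): chi2 = sum (O-E)^2/E with margins (17,17),(15,19)
        table = np.array([[12, 5], [3, 14]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        res = annotation_distribution_test(table[0], table[1])
        assert res.statistic == pytest.approx(by_hand, abs=1e-12)
        assert res.df == 1

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(25):
            table = rng.integers(1, 60, size=(2, 4))
            res = annotation_distribution_test(table[0], table[1])
            ref = stats.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-9)
            assert res.df == 3

    def test_fisher_mc_close_to_exact_on_2x2(self):
        table = np.array([[8, 2], [1, 9]])
        res = annotation_distribution_test(
            table[0], table[1], method="fisher_mc", n_mc_tables=40_000, seed=11
        )
        exact = stats.fisher_exact(table).pvalue
        assert res.p == pytest.approx(exact, abs=0.01)

    def test_fisher_mc_seeded_determinism(self):
        kw = dict(method="fisher_mc", n_mc_tables=5000, seed=4)
        assert (
            annotation_distribution_test([5, 9, 2], [7, 3, 8], **kw).p
            == annotation_distribution_test([5, 9, 2], [7, 3, 8], **kw).p
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            annotation_distribution_test([0, 5], [0, 7])


class TestMethylationProfile:
    def _meth(self, vals):
        return pd.DataFrame(
            {"tile_id": [f"t{i}" for i in range(len(vals))], "mean_meth": vals}
        )

    def test_identical_methylation_identical_summaries(self):
        assignments = pd.DataFrame(
            {"tile_id": ["t0", "t1", "t2", "t3"],
             "klass": ["promoter", "promoter", "exon", "exon"]}
        )
        meth = {"a": self._meth([0.5, 0.5, 0.5, 0.5]), "b": self._meth([0.5] * 4)}
        prof = annotation_methylation_profile(assignments, meth)
        assert (prof["median"] == 0.5).all() and (prof["q1"] == prof["q3"]).all()

    def test_single_class_single_condition_row(self):
        assignments = pd.DataFrame({"tile_id": ["t0", "t1"], "klass": ["intron"] * 2})
        prof = annotation_methylation_profile(
            assignments, {"only": self._meth([0.2, 0.4])}
        )
        assert len(prof) == 1 and prof["median"].iloc[0] == pytest.approx(0.3)

    def test_dmr_fraction_joined_per_class(self):
        assignments = pd.DataFrame(
            {"tile_id": ["t0", "t1", "t2"], "klass": ["exon", "exon", "promoter"]}
        )
        calls = pd.DataFrame({"tile_id": ["t0", "t1", "t2"], "is_dmr": [True, False, False]})
        prof = annotation_methylation_profile(
            assignments, {"c": self._meth([0.1, 0.2, 0.3])}, calls
        )
        by_class = prof.set_index("klass")["dmr_fraction"]
        assert by_class["exon"] == pytest.approx(0.5)
        assert by_class["promoter"] == pytest.approx(0.0)
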