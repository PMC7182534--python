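"""Known-truth properties of the synthetic methylome generator."""

import numpy as np
import pandas as pd
import pytest

from methtiles import (
    SynthParams,
    SynthTruth,
    crisp,
    generate_annotations_and_expression,
    generate_locus_sets,
    generate_methylomes,
    merge_replicates,
    merge_symmetric,
    paperlike,
    write_synthetic_dataset,
)
from methtiles.synth import _place_blocks, gene_layout

SMALL = dict(chrom_sizes={"chr1": 120_000}, n_background_loci=200, n_depleted_loci=30)


class TestDeterminism:
    def test_same_seed_identical_frames(self):
        p = paperlike(seed=11, **SMALL)
        d1, t1 = generate_methylomes(p)
        d2, t2 = generate_methylomes(p)
        pd.testing.assert_frame_equal(d1["lcl"][0], d2["lcl"][0])
        pd.testing.assert_frame_equal(t1.blocks, t2.blocks)

    def test_same_seed_byte_identical_files(self, tmp_path):
        p = crisp(seed=5, **SMALL)
        paths1 = write_synthetic_dataset(p, tmp_path / "a")
        paths2 = write_synthetic_dataset(p, tmp_path / "b")
        for key in ("truth", "expression", "background_loci"):
            assert open(paths1[key], "rb").read() == open(paths2[key], "rb").read()
        m1 = paths1["methylomes"]["lcl"][0]
        m2 = paths2["methylomes"]["lcl"][0]
        assert open(m1, "rb").read() == open(m2, "rb").read()

    def test_different_seeds_differ(self):
        d1, _ = generate_methylomes(paperlike(seed=1, **SMALL))
        d2, _ = generate_methylomes(paperlike(seed=2, **SMALL))
        assert not d1["lcl"][0].equals(d2["lcl"][0])


class TestBlocks:
    def test_blocks_disjoint_and_cover_requested_fraction(self):
        p = paperlike(seed=3, chrom_sizes={"chr1": 500_000}, block_fraction=0.4)
        _, truth = generate_methylomes(p)
        blk = truth.blocks.sort_values("start")
        assert (blk["start"].to_numpy()[1:] >= blk["end"].to_numpy()[:-1]).all()
        assert truth.block_fraction_of(p.chrom_sizes) == pytest.approx(0.4, abs=0.03)

    def test_zero_fraction_means_no_blocks(self):
        p = paperlike(seed=3, block_fraction=1e-9, **SMALL)
        _, truth = generate_methylomes(p)
        assert truth.blocks.empty

    def test_infeasible_packing_errors(self):
        with pytest.raises(ValueError):
            _place_blocks(
                SynthParams(chrom_sizes={"c": 30_000}, block_fraction=1.0, block_length=20_000),
                np.random.default_rng(0),
            )


class TestMethylomes:
    def test_null_case_conditions_share_law(self):
        # without blocks the two conditions have the same true methylation
        p = crisp(seed=9, block_fraction=1e-9, **SMALL)
        data, _ = generate_methylomes(p)
        for cond in ("activated", "lcl"):
            merged = merge_symmetric(merge_replicates(data[cond]))
            mean = (merged["meth"] * merged["cov"]).sum() / merged["cov"].sum()
            assert mean == pytest.approx(0.85, abs=0.02)

    def test_strand_split_and_coverage_regime(self):
        p = paperlike(seed=4, **SMALL)
        data, _ = generate_methylomes(p)
        rep = data["activated"][0]
        assert set(rep["strand"]) == {"+", "-"}
        merged = merge_symmetric(merge_replicates(data["activated"]))
        # mean merged coverage per symmetric CpG ~ coverage_lambda
        assert merged["cov"].mean() == pytest.approx(p.coverage_lambda, rel=0.1)

    def test_block_shift_visible_in_test_condition_only(self):
        p = crisp(seed=6, chrom_sizes={"chr1": 200_000}, promoters_exempt=False)
        data, truth = generate_methylomes(p)
        ref = merge_symmetric(merge_replicates(data["activated"]))
        test = merge_symmetric(merge_replicates(data["lcl"]))
        blk = truth.blocks
        in_blk = np.zeros(len(ref), dtype=bool)
        for _, b in blk.iterrows():
            in_blk |= (ref["pos"] >= b["start"]) & (ref["pos"] < b["end"])

        def wmean(df, mask):
            sub = df[mask & df["cov"].gt(0)]
            return (sub["meth"] * sub["cov"]).sum() / sub["cov"].sum()

        assert wmean(ref, in_blk) - wmean(test, in_blk) == pytest.approx(0.4, abs=0.03)
        assert wmean(ref, ~in_blk) - wmean(test, ~in_blk) == pytest.approx(0.0, abs=0.02)


class TestLocusSets:
    def test_null_rho_matches_background_law(self):
        p = paperlike(seed=8, depletion_rho=1.0, chrom_sizes={"chr1": 500_000},
                      n_background_loci=3000, n_depleted_loci=3000)
        _, truth = generate_methylomes(p)
        generate_locus_sets(p, truth)
        f_bg = truth.locus_flags["background"].mean()
        f_dep = truth.locus_flags["depleted"].mean()
        assert f_dep == pytest.approx(f_bg, abs=0.04)

    def test_rho_zero_avoids_blocks_entirely(self):
        p = paperlike(seed=8, depletion_rho=0.0, **SMALL)
        _, truth = generate_methylomes(p)
        generate_locus_sets(p, truth)
        assert truth.locus_flags["depleted"].sum() == 0

    def test_inside_block_fraction_closed_form(self):
        # rho=0.3, f=0.4 -> expected inside fraction 0.12/0.72 = 1/6
        p = paperlike(seed=2, depletion_rho=0.3, block_fraction=0.4,
                      chrom_sizes={"chr1": 1_000_000},
                      n_background_loci=100, n_depleted_loci=5000)
        _, truth = generate_methylomes(p)
        generate_locus_sets(p, truth)
        assert truth.locus_flags["depleted"].mean() == pytest.approx(1 / 6, abs=0.02)


class TestAnnotationsAndExpression:
    def test_layout_is_deterministic_and_disjoint_within_gene(self):
        p = paperlike(**SMALL)
        layout = gene_layout(p)
        pd.testing.assert_frame_equal(layout, gene_layout(p))
        for _, grp in layout.groupby("gene"):
            iv = grp.sort_values("start")
            assert (iv["start"].to_numpy()[1:] >= iv["end"].to_numpy()[:-1]).all()

    def test_zero_slope_gives_uncorrelated_expression(self):
        p = paperlike(seed=13, expr_slope=0.0, chrom_sizes={"chr1": 2_000_000})
        _, truth = generate_methylomes(p)
        generate_locus_sets(p, truth)
        *_, expression = generate_annotations_and_expression(p, truth)
        gt = truth.gene_truth
        r = np.corrcoef(gt["true_delta"], gt["logfc"])[0, 1]
        assert abs(r) < 0.25  # n = 100 genes

    def test_noiseless_unit_slope_perfect_correlation(self):
        p = paperlike(seed=13, expr_slope=1.0, expr_noise=1e-12,
                      chrom_sizes={"chr1": 500_000})
        _, truth = generate_methylomes(p)
        *_, expression = generate_annotations_and_expression(p, truth)
        gt = truth.gene_truth
        assert np.corrcoef(gt["true_delta"], gt["logfc"])[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_correlation(self):
        # r = a*sd(dm) / sqrt(a^2 var(dm) + sigma^2) for the emitted logfc
        alpha, sigma = 0.5, 1.0
        p = paperlike(seed=21, expr_slope=alpha, expr_noise=sigma,
                      chrom_sizes={"chr1": 14_000_000}, gene_pitch=7000)
        rng = np.random.default_rng(p.seed)
        truth = SynthTruth(blocks=_place_blocks(p, rng))
        *_, expression = generate_annotations_and_expression(p, truth)
        gt = truth.gene_truth
        assert len(gt) >= 1900
        var_dm = gt["true_delta"].var()
        expected_r = alpha * np.sqrt(var_dm) / np.sqrt(alpha**2 * var_dm + sigma**2)
        observed_r = np.corrcoef(gt["true_delta"], gt["logfc"])[0, 1]
        assert observed_r == pytest.approx(expected_r, abs=0.05)
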