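"""Synthetic methylome generator with known truth.

Emulates the data regime of an EBV-transformation WGBS study: a
high-methylation baseline (per-CpG Beta draws with mean ~0.85, the
activated-B-cell regime), large hypomethylated blocks covering a set
genome fraction in the test condition only (LCL-style, hence almost no
hypermethylated tiles), shallow read coverage (Poisson, mean ~6x,
strand-split so symmetric merging is exercised), locus sets with a
controlled propensity to avoid blocks, a simple gene/annotation layout
whose promoters can be exempted from the block shift, and expression
log fold-changes linearly coupled to gene-body methylation loss.

Every generator draws all randomness from one seed and emits truth
(block intervals, per-locus inside-block flags, per-gene true effects)
alongside the data; no pipeline stage reads truth.

Observation model: per strand and replicate, coverage ~
Poisson(lambda / (2 * n_replicates)) and methylated reads ~
Binomial(coverage, true methylation), i.e. a beta-binomial across
sites, so shallow coverage produces realistically noisy tile means.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .methio import SITE_COLUMNS

CONDITIONS = ("activated", "lcl")  # reference, test


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic study.

    Defaults are the "paperlike" regime: 46% of the genome in
    hypomethylated blocks, a 0.25 methylation drop inside blocks, and
    mean 6x merged coverage split over 3 replicates and 2 strands.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    cpg_spacing: float = 100.0        # mean bp between CpG dyads
    baseline_beta: tuple[float, float] = (8.5, 1.5)  # mean 0.85
    block_fraction: float = 0.46      # genome fraction inside blocks
    block_shift: float = 0.25         # methylation drop inside blocks (test cond.)
    block_length: int = 20_000        # bp per block
    block_grid: int = 1000            # block starts snap to this resolution
    coverage_lambda: float = 6.0      # mean merged coverage per symmetric CpG
    n_replicates: int = 3             # individuals per condition
    depletion_rho: float = 0.2        # in-block acceptance odds for the depleted set
    n_background_loci: int = 2000
    n_depleted_loci: int = 100
    gene_pitch: int = 20_000          # bp between successive gene starts
    promoter_width: int = 1000
    exon_width: int = 500
    intron_width: int = 2000
    n_exons: int = 3
    promoters_exempt: bool = True     # promoters escape the block shift
    expr_slope: float = 1.0           # alpha: logfc per unit true gene delta-meth
    expr_noise: float = 0.5           # sigma of the logfc noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.block_fraction <= 1.0:
            raise ValueError("block_fraction must be in [0, 1]")
        if not 0.0 < self.block_shift < 1.0:
            raise ValueError("block_shift must be in (0, 1)")
        if self.depletion_rho < 0:
            raise ValueError("depletion_rho must be >= 0")


def paperlike(**overrides) -> SynthParams:
    """Noisy realistic regime: f=0.46, d=0.25, mean coverage 6x."""
    return SynthParams(**overrides)


def crisp(**overrides) -> SynthParams:
    """Fast deterministic-ish regime for recovery tests: d=0.4, 20x."""
    kw = dict(block_shift=0.4, coverage_lambda=20.0)
    kw.update(overrides)
    return SynthParams(**kw)


@dataclass
class SynthTruth:
    """Ground truth emitted next to the data; never read by the pipeline."""

    blocks: pd.DataFrame                      # chrom, start, end
    locus_flags: dict[str, np.ndarray] = field(default_factory=dict)
    gene_truth: pd.DataFrame | None = None    # gene, block_frac, true_delta, logfc

    def block_fraction_of(self, chrom_sizes: dict[str, int]) -> float:
        total = sum(chrom_sizes.values())
        covered = int((self.blocks["end"] - self.blocks["start"]).sum())
        return covered / total


# ---------------------------------------------------------------- layout

def gene_layout(params: SynthParams) -> pd.DataFrame:
    """Deterministic gene structure: one gene every ``gene_pitch`` bp.

    Each gene is promoter (upstream of the TSS) followed by alternating
    exons and introns.  Returns one row per feature: chrom, start, end,
    gene, klass.  The layout is a pure function of the parameters, so
    the methylome generator and the annotation emitter always agree on
    where promoters are.
    """
    rows = []
    for chrom, length in params.chrom_sizes.items():
        body_len = (
            params.n_exons * params.exon_width
            + (params.n_exons - 1) * params.intron_width
        )
        tss = params.promoter_width  # leave room for the first promoter
        i = 0
        while tss + body_len <= length:
            gene = f"{chrom}_g{i}"
            rows.append((chrom, tss - params.promoter_width, tss, gene, "promoter"))
            at = tss
            for e in range(params.n_exons):
                rows.append((chrom, at, at + params.exon_width, gene, "exon"))
                at += params.exon_width
                if e < params.n_exons - 1:
                    rows.append((chrom, at, at + params.intron_width, gene, "intron"))
                    at += params.intron_width
            i += 1
            tss += params.gene_pitch
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "klass"])


def _place_blocks(params: SynthParams, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform non-overlapping blocks totalling ~block_fraction per chrom.

    Block starts snap to ``block_grid`` (default the 1-kb tile width) so
    the planted genome fraction is an exact property at tile scale —
    tiles are either wholly inside or wholly outside a block — which is
    what makes the planted fraction recoverable from tile-level calls
    without a boundary-tile bias.
    """
    rows = []
    grid = max(1, params.block_grid)
    for chrom, length in params.chrom_sizes.items():
        bl = min(params.block_length, length)
        n = int(round(params.block_fraction * length / bl))
        if n * bl > length:
            raise ValueError(
                f"cannot pack {n} blocks of {bl} bp into {chrom} ({length} bp); "
                "lower block_fraction or block_length"
            )
        if n == 0:
            continue
        slack = length - n * bl
        offsets = np.sort(rng.integers(0, slack // grid + 1, size=n)) * grid
        starts = offsets + bl * np.arange(n)
        for s in starts:
            rows.append((chrom, int(s), int(s + bl)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _in_intervals(pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of positions (one chromosome) in sorted disjoint intervals."""
    if intervals.empty:
        return np.zeros(len(pos), dtype=bool)
    starts = intervals["start"].to_numpy(dtype=np.int64)
    ends = intervals["end"].to_numpy(dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


# ------------------------------------------------------------ methylomes

def generate_methylomes(
    params: SynthParams,
) -> tuple[dict[str, list[pd.DataFrame]], SynthTruth]:
    """Per-condition, per-replicate strand-split CpG site tables + truth.

    Returns ({"activated": [rep1, rep2, ...], "lcl": [...]}, truth).
    Site tables are methcounts-shaped DataFrames (chrom, pos, strand,
    meth, cov) with the + strand C at p and the - strand C at p + 1.
    """
    rng = np.random.default_rng(params.seed)
    blocks = _place_blocks(params, rng)
    truth = SynthTruth(blocks=blocks)
    layout = gene_layout(params)
    promoters = layout[layout["klass"] == "promoter"]

    a, b = params.baseline_beta
    lam_strand = params.coverage_lambda / (2 * params.n_replicates)
    data: dict[str, list[pd.DataFrame]] = {c: [] for c in CONDITIONS}
    per_chrom: list[dict] = []

    for chrom, length in params.chrom_sizes.items():
        # CpG anchor positions via exponential spacing
        n_exp = int(length / params.cpg_spacing * 1.3) + 10
        gaps = rng.exponential(params.cpg_spacing, size=n_exp)
        pos = np.cumsum(gaps).astype(np.int64) + 1
        pos = np.unique(pos[pos < length - 1])

        base = rng.beta(a, b, size=len(pos))
        in_block = _in_intervals(pos, blocks[blocks["chrom"] == chrom])
        shifted = in_block.copy()
        if params.promoters_exempt:
            in_prom = _in_intervals(pos, promoters[promoters["chrom"] == chrom])
            shifted &= ~in_prom
        true_test = np.where(shifted, np.maximum(0.0, base - params.block_shift), base)
        per_chrom.append(
            {"chrom": chrom, "pos": pos, "true": {"activated": base, "lcl": true_test}}
        )

    for cond in CONDITIONS:
        for _rep in range(params.n_replicates):
            frames = []
            for entry in per_chrom:
                pos, true_m = entry["pos"], entry["true"][cond]
                n = len(pos)
                cov_p = rng.poisson(lam_strand, size=n)
                cov_m = rng.poisson(lam_strand, size=n)
                k_p = rng.binomial(cov_p, true_m)
                k_m = rng.binomial(cov_m, true_m)
                with np.errstate(invalid="ignore", divide="ignore"):
                    meth_p = np.where(cov_p > 0, k_p / np.maximum(cov_p, 1), np.nan)
                    meth_m = np.where(cov_m > 0, k_m / np.maximum(cov_m, 1), np.nan)
                plus = pd.DataFrame(
                    {"chrom": entry["chrom"], "pos": pos, "strand": "+",
                     "meth": meth_p, "cov": cov_p}
                )
                minus = pd.DataFrame(
                    {"chrom": entry["chrom"], "pos": pos + 1, "strand": "-",
                     "meth": meth_m, "cov": cov_m}
                )
                frames.append(
                    pd.concat([plus, minus]).sort_values(
                        ["chrom", "pos"], kind="mergesort", ignore_index=True
                    )
                )
            rep = pd.concat(frames, ignore_index=True)[SITE_COLUMNS]
            rep["pos"] = rep["pos"].astype(np.int64)
            rep["cov"] = rep["cov"].astype(np.int64)
            data[cond].append(rep)
    return data, truth


# ------------------------------------------------------------ locus sets

def generate_locus_sets(
    params: SynthParams, truth: SynthTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background SNP catalogue and a block-avoiding ("depleted") set.

    Background loci are uniform over the genome.  Depleted-set
    candidates are uniform but accepted with probability rho when
    inside a block and 1 otherwise, so the expected inside-block
    fraction is rho*f / (rho*f + 1 - f).  rho = 1 reproduces the
    background law (the calibration null); rho = 0 avoids blocks
    entirely.  Both sets and their true inside-block flags are recorded
    in ``truth.locus_flags``.
    """
    rng = np.random.default_rng(params.seed + 1)
    chroms = list(params.chrom_sizes)
    lengths = np.array([params.chrom_sizes[c] for c in chroms], dtype=np.float64)
    weights = lengths / lengths.sum()

    def draw_uniform(n: int) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=n, p=weights)
        pos = (rng.random(n) * lengths[ci]).astype(np.int64)
        return pd.DataFrame({"chrom": [chroms[i] for i in ci], "pos": pos})

    def flag(df: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(df), dtype=bool)
        for chrom, grp in df.groupby("chrom", sort=False):
            blk = truth.blocks[truth.blocks["chrom"] == chrom]
            out[grp.index.to_numpy()] = _in_intervals(
                grp["pos"].to_numpy(dtype=np.int64), blk
            )
        return out

    background = draw_uniform(params.n_background_loci).reset_index(drop=True)
    background["id"] = [f"bg{i}" for i in range(len(background))]

    kept: list[pd.DataFrame] = []
    n_kept = 0
    guard = 0
    while n_kept < params.n_depleted_loci:
        guard += 1
        if guard > 1000:
            raise ValueError("cannot generate requested depleted set (rho/f too restrictive)")
        cand = draw_uniform(max(2 * params.n_depleted_loci, 100)).reset_index(drop=True)
        inside = flag(cand)
        accept = np.where(inside, rng.random(len(cand)) < params.depletion_rho, True)
        cand = cand[accept]
        kept.append(cand)
        n_kept += len(cand)
    depleted = (
        pd.concat(kept, ignore_index=True).iloc[: params.n_depleted_loci].copy()
    )
    depleted["id"] = [f"dep{i}" for i in range(len(depleted))]
    depleted = depleted.reset_index(drop=True)

    truth.locus_flags["background"] = flag(background)
    truth.locus_flags["depleted"] = flag(depleted)
    return background, depleted


# --------------------------------------------- annotations and expression

def generate_annotations_and_expression(
    params: SynthParams, truth: SynthTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Annotation intervals, gene models, and a coupled expression table.

    Returns (annotations, genes, expression):

    * annotations — chrom, start, end, klass (promoter/exon/intron),
      gene: the deterministic layout from :func:`gene_layout`;
    * genes — chrom, start, end, name: the gene body (promoter through
      last exon) per gene, for closest-gene lookups;
    * expression — gene, logfc with
      logfc = expr_slope * true_delta + Normal(0, expr_noise), where
      true_delta is the expected methylation loss over the gene's
      exons+introns (block overlap fraction times block_shift).
      Promoters are exempt from the shift, so promoter methylation
      carries no expression signal.

    The per-gene truth (block overlap, true delta, emitted logfc) is
    stored in ``truth.gene_truth``.
    """
    rng = np.random.default_rng(params.seed + 2)
    layout = gene_layout(params)
    body = layout[layout["klass"].isin(["exon", "intron"])]

    overlaps = np.zeros(len(body), dtype=np.float64)
    for chrom, grp in body.groupby("chrom", sort=False):
        blk = truth.blocks[truth.blocks["chrom"] == chrom]
        if blk.empty:
            continue
        bs = blk["start"].to_numpy(dtype=np.int64)
        be = blk["end"].to_numpy(dtype=np.int64)
        s = grp["start"].to_numpy(dtype=np.int64)
        e = grp["end"].to_numpy(dtype=np.int64)
        ov = np.zeros(len(grp))
        for j in range(len(bs)):
            ov += np.maximum(0, np.minimum(e, be[j]) - np.maximum(s, bs[j]))
        overlaps[body.index.get_indexer(grp.index)] = ov

    body = body.assign(_ov=overlaps, _len=(body["end"] - body["start"]).astype(float))
    per_gene = body.groupby("gene", sort=False).agg(ov=("_ov", "sum"), ln=("_len", "sum"))
    per_gene["block_frac"] = per_gene["ov"] / per_gene["ln"]
    per_gene["true_delta"] = per_gene["block_frac"] * params.block_shift
    per_gene["logfc"] = params.expr_slope * per_gene["true_delta"] + rng.normal(
        0.0, params.expr_noise, size=len(per_gene)
    )

    genes = (
        layout.groupby("gene", sort=False)
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
        .rename(columns={"gene": "name"})[["chrom", "start", "end", "name"]]
    )
    expression = per_gene.reset_index()[["gene", "logfc"]]
    truth.gene_truth = per_gene.reset_index()[
        ["gene", "block_frac", "true_delta", "logfc"]
    ]
    annotations = layout[["chrom", "start", "end", "klass", "gene"]].copy()
    return annotations, genes, expression


# ------------------------------------------------------------- file I/O

def write_synthetic_dataset(params: SynthParams, outdir: str | Path) -> dict[str, object]:
    """Generate a complete dataset and write it in the pipeline's input
    formats (methcounts TSV per condition/replicate, BED locus sets and
    annotations, chrom.sizes, expression TSV, truth JSON, and a ready
    run-config YAML).  Returns the path map.  Byte-identical for a
    fixed seed."""
    from .methio import write_methcounts  # local import to avoid cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data, truth = generate_methylomes(params)
    background, depleted = generate_locus_sets(params, truth)
    annotations, genes, expression = generate_annotations_and_expression(params, truth)

    paths: dict[str, object] = {}
    cond_paths: dict[str, list[str]] = {}
    for cond, reps in data.items():
        cond_paths[cond] = []
        for i, rep in enumerate(reps, start=1):
            p = outdir / f"{cond}_rep{i}.methcounts.tsv"
            write_methcounts(rep, p)
            cond_paths[cond].append(str(p))
    paths["methylomes"] = cond_paths

    sizes_path = outdir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, length in params.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_sizes"] = str(sizes_path)

    for name, df in (("background", background), ("depleted", depleted)):
        p = outdir / f"{name}_loci.bed"
        bed = pd.DataFrame(
            {"chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1, "name": df["id"]}
        )
        bed.to_csv(p, sep="\t", header=False, index=False)
        paths[f"{name}_loci"] = str(p)

    ann_path = outdir / "annotations.bed"
    pd.DataFrame(
        {
            "chrom": annotations["chrom"], "start": annotations["start"],
            "end": annotations["end"], "name": annotations["klass"],
            "score": 0, "strand": ".",
        }
    ).to_csv(ann_path, sep="\t", header=False, index=False)
    paths["annotations"] = str(ann_path)

    genes_path = outdir / "genes.bed"
    genes.to_csv(genes_path, sep="\t", header=False, index=False)
    paths["genes"] = str(genes_path)

    expr_path = outdir / "expression.tsv"
    expression.to_csv(expr_path, sep="\t", index=False)
    paths["expression"] = str(expr_path)

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "blocks": truth.blocks.to_dict(orient="records"),
                "locus_flags": {k: v.tolist() for k, v in truth.locus_flags.items()},
                "gene_truth": truth.gene_truth.to_dict(orient="records"),
                "params": {
                    k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(params).items()
                },
            },
            fh,
            indent=1,
        )
    paths["truth"] = str(truth_path)

    config = {
        "chrom_sizes": str(sizes_path),
        "conditions": cond_paths,
        "comparisons": [["activated", "lcl"]],
        "locus_sets": {"depleted": str(paths["depleted_loci"])},
        "background": str(paths["background_loci"]),
        "annotations": str(ann_path),
        "genes": str(genes_path),
        "expression": str(expr_path),
        "reference": "activated",
        "test": "lcl",
        "output_dir": str(outdir / "results"),
        "analysis": {"rng_seed": params.seed},
        "excluded_chroms": [],
    }
    cfg_path = outdir / "run_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["config"] = str(cfg_path)
    return paths
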