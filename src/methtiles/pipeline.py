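"""End-to-end orchestration from a YAML run configuration.

Stages, in method order:

1. load methylomes — read methcounts files per condition/replicate,
   pool replicates, merge symmetric CpGs, apply the chromosome filter;
2. tile — genome-wide grid + SNP-centred windows per locus set, with
   regional methylation per condition;
3. dmr — threshold calls per comparison, per-locus-set summaries;
4. deplete — resampling depletion test of each locus set against the
   background catalogue;
5. annotate — annotation distributions of locus lists (vs background)
   and per-class methylation profiles;
6. integrate — expression/methylation correlation and DMR-rate-by-DE
   tables (skipped with a warning when no expression table is given).

Every numeric output lands in ``output_dir`` as TSV/JSON stamped with
the config hash and seed; a stage failure aborts the run naming the
stage, with earlier outputs retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import diffmeth, enrichment, exprmeth, methio, tiling

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated file paths and analysis settings for one pipeline run."""

    chrom_sizes: str
    conditions: dict[str, list[str]]          # condition -> methcounts paths
    comparisons: list[tuple[str, str]]        # (reference, test) pairs
    background: str | None = None             # background locus BED
    locus_sets: dict[str, str] = field(default_factory=dict)
    annotations: str | None = None            # BED with class in name column
    genes: str | None = None                  # BED with gene label in name column
    expression: str | None = None             # TSV gene, logfc
    output_dir: str = "methtiles_out"
    analysis: tiling.AnalysisConfig = field(default_factory=tiling.AnalysisConfig)
    excluded_chroms: frozenset[str] = methio.DEFAULT_EXCLUDED_CHROMS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        analysis = tiling.AnalysisConfig(**raw.get("analysis", {}))
        comparisons = [tuple(c) for c in raw.get("comparisons", [])]
        if not comparisons and raw.get("reference") and raw.get("test"):
            comparisons = [(raw["reference"], raw["test"])]
        cfg = cls(
            chrom_sizes=raw["chrom_sizes"],
            conditions={k: list(v) for k, v in raw["conditions"].items()},
            comparisons=comparisons,
            background=raw.get("background"),
            locus_sets=dict(raw.get("locus_sets", {})),
            annotations=raw.get("annotations"),
            genes=raw.get("genes"),
            expression=raw.get("expression"),
            output_dir=raw.get("output_dir", "methtiles_out"),
            analysis=analysis,
            excluded_chroms=frozenset(raw.get("excluded_chroms", methio.DEFAULT_EXCLUDED_CHROMS)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.chrom_sizes, *(p for ps in self.conditions.values() for p in ps)]
        paths += [p for p in (self.background, self.annotations, self.genes, self.expression) if p]
        paths += list(self.locus_sets.values())
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        for ref, test in self.comparisons:
            for cond in (ref, test):
                if cond not in self.conditions:
                    raise ValueError(f"comparison references unknown condition {cond!r}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "chrom_sizes": self.chrom_sizes,
                "conditions": self.conditions,
                "comparisons": [list(c) for c in self.comparisons],
                "background": self.background,
                "locus_sets": self.locus_sets,
                "annotations": self.annotations,
                "genes": self.genes,
                "expression": self.expression,
                "analysis": self.analysis.__dict__,
                "excluded_chroms": sorted(self.excluded_chroms),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    """Wraps a failure so the report names the failing stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _read_locus_bed(path: str) -> pd.DataFrame:
    bed = methio.read_bed(path)
    out = pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"]})
    out["id"] = bed["name"] if "name" in bed.columns else [f"locus{i}" for i in range(len(bed))]
    return out


def load_condition_sites(
    paths: list[str], chrom_filter: methio.ChromFilter
) -> pd.DataFrame:
    """Replicate methcounts files -> pooled, symmetric-merged, filtered sites."""
    reps = [methio.read_methcounts(p) for p in paths]
    merged = methio.merge_replicates(reps)
    sym = methio.merge_symmetric(merged)
    return methio.apply_chrom_filter(sym, chrom_filter)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the in-memory report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.analysis.rng_seed}
    report: dict = {"stamp": stamp}
    chrom_filter = methio.ChromFilter(excluded=config.excluded_chroms)
    acfg = config.analysis

    stage = "load"
    try:
        chrom_sizes = {
            c: n
            for c, n in methio.read_chrom_sizes(config.chrom_sizes).items()
            if not chrom_filter.is_excluded(c)
        }
        sites = {
            cond: load_condition_sites(paths, chrom_filter)
            for cond, paths in config.conditions.items()
        }

        stage = "tile"
        grid = tiling.make_grid_tiles(chrom_sizes, acfg)
        grid_meth = {c: tiling.region_methylation(grid, s) for c, s in sites.items()}
        for cond, gm in grid_meth.items():
            gm.to_csv(outdir / f"tile_methylation_{cond}.tsv", sep="\t", index=False)
        locus_tiles = {}
        for name, path in config.locus_sets.items():
            loci = methio.apply_chrom_filter(_read_locus_bed(path), chrom_filter)
            locus_tiles[name] = tiling.make_snp_tiles(loci, chrom_sizes, acfg)
        if config.background:
            loci = methio.apply_chrom_filter(_read_locus_bed(config.background), chrom_filter)
            locus_tiles["background"] = tiling.make_snp_tiles(loci, chrom_sizes, acfg)

        stage = "dmr"
        report["comparisons"] = {}
        for ref, test in config.comparisons:
            key = f"{test}_vs_{ref}"
            grid_calls = diffmeth.call_dmrs(grid_meth[ref], grid_meth[test], acfg)
            summaries = {"genome_wide": diffmeth.summarize_dmrs(grid_calls, len(grid))}
            set_calls = {}
            for name, tiles in locus_tiles.items():
                m_ref = tiling.region_methylation(tiles, sites[ref])
                m_test = tiling.region_methylation(tiles, sites[test])
                calls = diffmeth.call_dmrs(m_ref, m_test, acfg)
                set_calls[name] = calls
                summaries[name] = diffmeth.summarize_dmrs(calls, len(tiles))
            table = diffmeth.summary_table(summaries)
            table.to_csv(outdir / f"dmr_summary_{key}.tsv", sep="\t", index=False)
            grid_calls.to_csv(outdir / f"dmr_calls_{key}.tsv", sep="\t", index=False)
            report["comparisons"][key] = {
                "grid_calls": grid_calls,
                "set_calls": set_calls,
                "summaries": summaries,
            }

        if len(config.comparisons) >= 2:
            (r1, t1), (r2, t2) = config.comparisons[:2]
            a = report["comparisons"][f"{t1}_vs_{r1}"]["grid_calls"]
            b = report["comparisons"][f"{t2}_vs_{r2}"]["grid_calls"]
            report["dmr_overlap"] = diffmeth.dmr_overlap(a, b)
            with open(outdir / "dmr_overlap.json", "w") as fh:
                json.dump({"pct_a_in_b": report["dmr_overlap"][0],
                           "pct_b_in_a": report["dmr_overlap"][1], **stamp}, fh)

        stage = "deplete"
        if config.background and config.locus_sets:
            report["depletion"] = {}
            for key, comp in report["comparisons"].items():
                bg_calls = comp["set_calls"]["background"]
                for name in config.locus_sets:
                    res = enrichment.depletion_from_summary(
                        comp["summaries"][name], bg_calls, acfg
                    )
                    report["depletion"][f"{key}/{name}"] = res
                    with open(outdir / f"depletion_{key}_{name}.json", "w") as fh:
                        fh.write(res.to_json())

        stage = "annotate"
        if config.annotations:
            ann_bed = methio.read_bed(config.annotations)
            track = ann.AnnotationTrack(
                promoters=ann_bed[ann_bed["name"] == "promoter"],
                exons=ann_bed[ann_bed["name"] == "exon"],
                introns=ann_bed[ann_bed["name"] == "intron"],
            )
            dists = {}
            for name, tiles in locus_tiles.items():
                assigned = ann.assign_annotation(ann.tile_midpoints(tiles), track)
                dists[name] = ann.class_counts(assigned)
            report["annotation_counts"] = dists
            pd.DataFrame(dists).to_csv(outdir / "annotation_counts.tsv", sep="\t")
            if "background" in dists:
                tests = {}
                for name in config.locus_sets:
                    try:
                        tests[name] = ann.annotation_distribution_test(
                            dists[name], dists["background"], method="chi_square"
                        )
                    except ValueError as exc:
                        logger.warning("annotation test for %s skipped: %s", name, exc)
                report["annotation_tests"] = tests
            grid_assigned = ann.assign_annotation(ann.tile_midpoints(grid), track)
            first_key = next(iter(report["comparisons"]))
            profile = ann.annotation_methylation_profile(
                grid_assigned[["tile_id", "klass"]],
                grid_meth,
                report["comparisons"][first_key]["grid_calls"],
            )
            profile.to_csv(outdir / "annotation_methylation_profile.tsv", sep="\t", index=False)
            report["annotation_profile"] = profile

        stage = "integrate"
        if config.expression and config.annotations and config.genes:
            ref, test = config.comparisons[0]
            ann_bed = methio.read_bed(config.annotations).rename(columns={"name": "klass"})
            genes = methio.read_bed(config.genes)
            expression = pd.read_csv(config.expression, sep="\t")
            rows = exprmeth.annotation_meth_expr(
                ann_bed[["chrom", "start", "end", "klass"]],
                sites[ref], sites[test], genes, expression, acfg,
            )
            correlations = {
                k: exprmeth.correlate_meth_expression(rows, k)
                for k in exprmeth.EXPR_CLASSES
            }
            rates = exprmeth.dmr_rate_by_de_class(rows, acfg)
            report["expression"] = {
                "rows": rows,
                "class_summary": exprmeth.expression_class_summary(
                    exprmeth.classify_expression(expression, acfg)
                ),
                "correlations": correlations,
                "dmr_rates": rates,
            }
            with open(outdir / "expression_integration.json", "w") as fh:
                json.dump(
                    {
                        "class_summary": report["expression"]["class_summary"],
                        "correlations": {k: {"r": v[0], "n": v[1]} for k, v in correlations.items()},
                        "dmr_rates": {
                            k: {kk: vv for kk, vv in v.items() if kk not in ("table", "chi_square")}
                            for k, v in rates.items()
                        },
                        **stamp,
                    },
                    fh,
                )
        elif config.expression is None:
            logger.warning("no expression table configured; integration stage skipped")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(outdir / "run_stamp.json", "w") as fh:
        json.dump(stamp, fh)
    return report
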